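import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


FIXTURE_KGML = """<?xml version="1.0"?>
<pathway name="path:hsa90001" org="hsa" number="90001" title="fixture pathway">
  <entry id="1" name="cpd:C00022" type="compound">
    <graphics name="C00022" x="100" y="300" width="8" height="8" type="circle"/>
  </entry>
  <entry id="2" name="cpd:C00024" type="compound">
    <graphics name="C00024" x="250" y="300" width="8" height="8" type="circle"/>
  </entry>
  <entry id="3" name="cpd:C00036" type="compound">
    <graphics name="C00036" x="400" y="300" width="8" height="8" type="circle"/>
  </entry>
  <entry id="4" name="hsa:1737 hsa:1738" type="gene" link="https://www.kegg.jp/entry/hsa:1737">
    <graphics name="DLAT..." x="175" y="200" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="5" name="hsa:5091" type="gene">
    <graphics name="PC" x="325" y="200" width="46" height="17" type="rectangle"/>
  </entry>
  <reaction id="4" name="rn:R00209" type="irreversible">
    <substrate id="1" name="cpd:C00022"/>
    <product id="2" name="cpd:C00024"/>
  </reaction>
  <reaction id="5" name="rn:R00344" type="reversible">
    <substrate id="1" name="cpd:C00022"/>
    <product id="3" name="cpd:C00036"/>
  </reaction>
  <reaction id="5" name="rn:R00345" type="irreversible">
    <substrate id="2" name="cpd:C00024"/>
    <product id="3" name="cpd:C00036"/>
  </reaction>
  <relation entry1="4" entry2="5" type="ECrel">
    <subtype name="compound" value="2"/>
  </relation>
</pathway>
"""


@pytest.fixture
def fixture_kgml_path(tmp_path):
    path = tmp_path / "hsa90001.xml"
    path.write_text(FIXTURE_KGML)
    return path
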