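"""Independent oracles used to cross-check the implementation.

Each oracle is written as a direct, brute-force restatement of the rule it
checks — deliberately sharing no code with the package modules.
"""

from itertools import combinations

USABLE = {"mitochondria", "cytoplasm", "nucleus", "secretory"}


def consensus_oracle(subcell: str, hpa: str, busca: str) -> str:
    """Rule-hierarchy restatement: agreeing pair > predictor vote > lone vote."""
    votes = [subcell, hpa, busca]
    usable_votes = [v for v in votes if v in USABLE]
    for a, b in combinations(usable_votes, 2):
        if a == b:
            return a
    if busca in USABLE:
        return busca
    if len(usable_votes) == 1:
        return usable_votes[0]
    return "unknown"


def confusion_oracle(pred: dict, truth: dict) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) for mitochondria-vs-rest via scikit-learn."""
    from sklearn.metrics import confusion_matrix

    shared = sorted(g for g in truth if g in pred
                    and pred[g] in USABLE and truth[g] in USABLE)
    y_true = [int(truth[g] == "mitochondria") for g in shared]
    y_pred = [int(pred[g] == "mitochondria") for g in shared]
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return int(tp), int(fp), int(tn), int(fn)


def rect_overlap(a, b) -> bool:
    """Strict interior intersection of two (x, y, w, h) center-based boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return (abs(ax - bx) < (aw + bw) / 2) and (abs(ay - by) < (ah + bh) / 2)
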