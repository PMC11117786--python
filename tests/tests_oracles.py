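"""Independent brute-force oracles used to cross-check ranking metrics."""

import numpy as np


def pair_counting_auc(scores, labels):
    """O(n^2) Mann-Whitney estimator: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def enumeration_ap(scores, labels):
    """Average precision by exhaustive enumeration of score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        k = int(np.sum(s >= t))
        tp = y[:k].sum()
        ap += (tp / n_pos - prev_recall) * (tp / k)
        prev_recall = tp / n_pos
    return ap
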