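"""Independent scalar reference for the fuzzy-rank fusion rule.

Pure-Python, loop-by-loop transliteration of the defining equations
(Gaussian-complement rank, top-K membership, penalized rank sum and
confidence-sum complement, multiplicative final score, argmin).  Kept
free of numpy and of the production code paths so it can serve as an
oracle in equivalence tests.
"""

import math


def frlf_scalar(rows, k=1, rank_penalty=0.33, conf_penalty=0.05, variance=1.0):
    """rows: list of N lists of C normalized confidences.

    Returns (rank_sums, conf_complements, final_scores, predicted_class).
    """
    n = len(rows)
    c = len(rows[0])
    ranks = [
        [1.0 - math.exp(-((rows[i][j] - 1.0) ** 2) / (2.0 * variance)) for j in range(c)]
        for i in range(n)
    ]
    top_k = []
    for i in range(n):
        order = sorted(range(c), key=lambda j: (ranks[i][j], j))
        top_k.append(set(order[:k]))
    rank_sums, conf_complements, final_scores = [], [], []
    for j in range(c):
        rs = sum(ranks[i][j] if j in top_k[i] else rank_penalty for i in range(n))
        css = 1.0 - sum(rows[i][j] if j in top_k[i] else conf_penalty for i in range(n)) / n
        rank_sums.append(rs)
        conf_complements.append(css)
        final_scores.append(rs * css)
    predicted = min(range(c), key=lambda j: (final_scores[j], j))
    return rank_sums, conf_complements, final_scores, predicted
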