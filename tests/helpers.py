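"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (literal
lookup tables, itertools enumeration, plain loops) and never calls into the
package, so it can serve as an independent cross-check of the implementation.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np

# Standard genetic code as a literal table (independent of Bio.Data).
_CODE_BLOCK = """
TTT F  TCT S  TAT Y  TGT C
TTC F  TCC S  TAC Y  TGC C
TTA L  TCA S  TAA *  TGA *
TTG L  TCG S  TAG *  TGG W
CTT L  CCT P  CAT H  CGT R
CTC L  CCC P  CAC H  CGC R
CTA L  CCA P  CAA Q  CGA R
CTG L  CCG P  CAG Q  CGG R
ATT I  ACT T  AAT N  AGT S
ATC I  ACC T  AAC N  AGC S
ATA I  ACA T  AAA K  AGA R
ATG M  ACG T  AAG K  AGG R
GTT V  GCT A  GAT D  GGT G
GTC V  GCC A  GAC D  GGC G
GTA V  GCA A  GAA E  GGA G
GTG V  GCG A  GAG E  GGG G
"""

ORACLE_CODE: dict[str, str] = {}
for _line in _CODE_BLOCK.strip().splitlines():
    _tokens = _line.split()
    for _codon, _aa in zip(_tokens[::2], _tokens[1::2]):
        ORACLE_CODE[_codon] = _aa


def oracle_classify(ref: str, alt: str) -> tuple[str, int]:
    """Classification from the literal code table."""
    if ORACLE_CODE[alt] == "*":
        vclass = "nonsense"
    elif ORACLE_CODE[alt] == ORACLE_CODE[ref]:
        vclass = "silent"
    else:
        vclass = "missense"
    return vclass, sum(a != b for a, b in zip(ref, alt))


def brute_force_effect(group_a, group_b) -> tuple[float, float, float]:
    """Median standardized difference by explicit pair enumeration.

    ``group_a`` and ``group_b`` are 1-D sequences of values for one variant.
    Returns (diff_btw, diff_win, effect) using exact medians over all
    cross-group pairs and within-group absolute pairwise differences.
    """
    cross = [b - a for a in group_a for b in group_b]
    within_a = [abs(x - y) for x, y in itertools.combinations(group_a, 2)]
    within_b = [abs(x - y) for x, y in itertools.combinations(group_b, 2)]
    diff_btw = statistics.median(cross)
    diff_win = max(statistics.median(within_a), statistics.median(within_b))
    all_within = [d for d in within_a + within_b if d > 0]
    eps = min(all_within) if all_within else 1e-8
    return diff_btw, diff_win, diff_btw / max(diff_win, eps)


def exact_wilcoxon_p(x, y, sidedness: str = "two-sided") -> float:
    """Exact rank-sum p by full enumeration of rank assignments (no ties).

    The U statistic of ``x`` is compared against its permutation distribution
    over all C(n+m, n) splits of the pooled ranks.
    """
    pooled = sorted(list(x) + list(y))
    n, m = len(x), len(y)

    def u_of(subset) -> float:
        # U = number of (xi, yj) pairs with xi > yj, via rank sum
        ranks = [pooled.index(v) + 1 for v in subset]
        return sum(ranks) - n * (n + 1) / 2

    observed = u_of(sorted(x))
    dist = [
        u_of([pooled[i] for i in combo])
        for combo in itertools.combinations(range(n + m), n)
    ]
    total = len(dist)
    if sidedness == "two-sided":
        lower = sum(u <= observed for u in dist)
        upper = sum(u >= observed for u in dist)
        return min(1.0, 2 * min(lower, upper) / total)
    if sidedness == "greater":
        return sum(u >= observed for u in dist) / total
    if sidedness == "less":
        return sum(u <= observed for u in dist) / total
    raise ValueError(sidedness)


def spreadsheet_iqlr(freqs: np.ndarray) -> np.ndarray:
    """Four-step IQLR across layers, written out step by step."""
    freqs = np.asarray(freqs, dtype=float)
    n_var, n_layer = freqs.shape
    closed = np.empty_like(freqs)
    for j in range(n_layer):  # step 1: reclose each layer
        closed[:, j] = freqs[:, j] / freqs[:, j].sum()
    clr = np.empty_like(closed)
    for j in range(n_layer):  # step 2: CLR per layer
        logs = np.log(closed[:, j])
        clr[:, j] = logs - logs.mean()
    variances = np.array([np.var(clr[i, :], ddof=1) for i in range(n_var)])  # step 3
    q1 = np.quantile(variances, 0.25)
    q3 = np.quantile(variances, 0.75)
    selected = [i for i in range(n_var) if q1 <= variances[i] <= q3]
    iqlr = np.empty_like(closed)
    for j in range(n_layer):  # step 4: log ratio to the geometric mean of selected
        geo = np.exp(np.mean([np.log(closed[i, j]) for i in selected]))
        iqlr[:, j] = np.log(closed[:, j] / geo)
    return iqlr
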