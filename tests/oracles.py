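"""Independent brute-force reference implementations used only by tests.

Deliberately naive: per-position string scanning, exhaustive chain
enumeration, textbook expected-count chi-square and explicit binomial
tail sums, so they share no code with the package paths they check.
"""

from __future__ import annotations

from math import comb

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
H = set("ACT")


def revcomp(seq: str) -> str:
    return "".join(COMP.get(b, "N") for b in reversed(seq))


def naive_context(b1: str, b2: str) -> str:
    """Context from the two downstream bases, by literal rule lookup."""
    if b1 == "G":
        return "CG"
    if b1 in H and b2 == "G":
        return "CHG"
    if b1 in H and b2 in H:
        return "CHH"
    return "NA"


def naive_scan(seq: str):
    """All cytosine sites of one sequence via per-position string checks.

    Yields (pos, strand, context, neighborhood) in position order.
    The reverse strand is scanned on the literal reverse complement and
    coordinates mapped back.
    """
    seq = seq.upper()
    seq = "".join(b if b in "ACGTN" else "N" for b in seq)
    n = len(seq)
    padded = "N" * 4 + seq + "N" * 4
    fwd = {}
    for i, base in enumerate(seq):
        if base == "C":
            b1 = seq[i + 1] if i + 1 < n else "N"
            b2 = seq[i + 2] if i + 2 < n else "N"
            fwd[(i, "+")] = (naive_context(b1, b2), padded[i : i + 9])
    rc = revcomp(seq)
    for j, base in enumerate(rc):
        if base == "C":
            b1 = rc[j + 1] if j + 1 < n else "N"
            b2 = rc[j + 2] if j + 2 < n else "N"
            i = n - 1 - j
            rc_padded = "N" * 4 + rc + "N" * 4
            fwd[(i, "-")] = (naive_context(b1, b2), rc_padded[j : j + 9])
    for (pos, strand), (ctx, neigh) in sorted(fwd.items()):
        yield pos, strand, ctx, neigh


def binom_sf_exact(k: int, n: int, p: float) -> float:
    """P(X >= k) for Binomial(n, p), by explicit summation."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def chi2_expected_counts(a: int, b: int, c: int, d: int) -> float:
    """Pearson statistic via the textbook sum over expected counts."""
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    obs = ((a, b), (c, d))
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def brute_force_chains(positions, max_gap: int):
    """All maximal chains by exhaustive pairwise checking.

    A chain is a maximal run of consecutive positions with every adjacent
    gap strictly below `max_gap`; enumerated by testing every candidate
    (start, end) slice for internal gaps and outward extensibility.
    """
    positions = sorted(positions)
    n = len(positions)
    chains = []
    for i in range(n):
        for j in range(i, n):
            internal_ok = all(
                positions[k + 1] - positions[k] < max_gap for k in range(i, j)
            )
            left_ext = i > 0 and positions[i] - positions[i - 1] < max_gap
            right_ext = j < n - 1 and positions[j + 1] - positions[j] < max_gap
            if internal_ok and not left_ext and not right_ext:
                chains.append((positions[i], positions[j]))
    return chains


def brute_force_candidates(positions, signs, mc_a, mc_b, max_gap, min_len, max_len, min_sites):
    """Candidate intervals by exhaustive chain enumeration plus filters.

    Chains additionally break at per-site difference sign flips when signs
    are given (parallel to positions).
    """
    positions = list(positions)
    if signs is None:
        runs = brute_force_chains(positions, max_gap)
    else:
        # break the position list into maximal same-sign runs, then chain
        runs = []
        block = [0]
        for i in range(1, len(positions)):
            gap_break = positions[i] - positions[i - 1] >= max_gap
            sign_break = signs[i] != signs[i - 1]
            if gap_break or sign_break:
                runs_block = [(positions[block[0]], positions[block[-1]])]
                runs.extend(runs_block)
                block = [i]
            else:
                block.append(i)
        if block and positions:
            runs.append((positions[block[0]], positions[block[-1]]))
    out = []
    for first, last in runs:
        span = last - first + 1
        if not (min_len <= span <= max_len):
            continue
        na = sum(1 for p in mc_a if first <= p <= last)
        nb = sum(1 for p in mc_b if first <= p <= last)
        if max(na, nb) < min_sites:
            continue
        out.append((first, last))
    return out
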