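"""Enumerate and classify every cytosine of a genome by sequence context.

Plant methylomes are read in three sequence contexts — CG, CHG and CHH,
where H is A, C or T — defined by the two bases immediately 3' of the
cytosine on its own strand.  Both strands are scanned: a reference G is a
cytosine on the reverse strand whose context is read on the reverse
complement.  Each site also carries its 9-bp reference neighbourhood
(cytosine at offset 4, 5'->3' on the cytosine's strand, N-padded at
sequence ends) for base-composition analyses around methylated vs
unmethylated cytosines.

Coordinates are 0-based internally; text reports are written 1-based by
:mod:`bsmeth.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as bio

CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T, _N = 65, 67, 71, 84, 78
_COMPLEMENT = np.full(256, _N, dtype=np.uint8)
for _x, _y in ((_A, _T), (_T, _A), (_C, _G), (_G, _C), (_N, _N)):
    _COMPLEMENT[_x] = _y

_H_BASES = frozenset("ACT")


@dataclass(frozen=True)
class CytosineSite:
    """One reference cytosine: position, strand, context and 9-bp window."""

    chrom: str
    pos: int  # 0-based, forward coordinate of the C (a G for '-' sites)
    strand: str
    context: str  # CG | CHG | CHH | NA
    neighborhood: str  # length 9, cytosine at index 4, 5'->3' on own strand


def classify_context(base: str, next1: str, next2: str) -> str:
    """Classify one cytosine from the two bases 3' of it on its own strand.

    CG is decided by the first downstream base alone; CHG/CHH need both.
    Any N (or missing base, passed as 'N') where a decision is still needed
    makes the context NA.
    """
    if base != "C":
        raise ValueError(f"classify_context called on non-cytosine base {base!r}")
    if next1 == "G":
        return "CG"
    if next1 not in _H_BASES:
        return "NA"
    if next2 == "G":
        return "CHG"
    if next2 in _H_BASES:
        return "CHH"
    return "NA"


def _normalize_sequence(seq: str, iupac_policy: str = "map_to_n") -> np.ndarray:
    """Uppercase a sequence into a uint8 array; handle non-ACGTN codes.

    iupac_policy 'map_to_n' replaces ambiguity codes with N; 'error' raises.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    known = np.isin(arr, (_A, _C, _G, _T, _N))
    if not known.all():
        if iupac_policy == "error":
            bad = bytes(sorted(set(arr[~known]))).decode("ascii")
            raise ValueError(f"non-ACGTN bases present: {bad!r}")
        arr[~known] = _N
    return arr


def _context_codes(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Vectorised context classification; returns indices into CONTEXTS + NA.

    0=CG 1=CHG 2=CHH 3=NA, given the two downstream bases on the C strand.
    """
    is_h1 = (first == _A) | (first == _C) | (first == _T)
    is_h2 = (second == _A) | (second == _C) | (second == _T)
    out = np.full(first.shape, 3, dtype=np.int8)
    out[first == _G] = 0
    out[is_h1 & (second == _G)] = 1
    out[is_h1 & is_h2] = 2
    return out


def _windows_to_strings(mat: np.ndarray) -> list[str]:
    flat = mat.tobytes().decode("ascii")
    w = mat.shape[1]
    return [flat[i : i + w] for i in range(0, len(flat), w)]


def enumerate_cytosines(
    genome: dict[str, str] | str,
    iupac_policy: str = "map_to_n",
    with_neighborhood: bool = True,
) -> pd.DataFrame:
    """Emit every cytosine on both strands of a genome, with context.

    Parameters
    ----------
    genome:
        Mapping of sequence name to sequence, or a FASTA path.
    iupac_policy:
        'map_to_n' (default) treats ambiguity codes as N; 'error' rejects them.
    with_neighborhood:
        Whether to build the 9-bp neighbourhood strings (the only costly part).

    Returns a DataFrame (chrom, pos, strand, context, neighborhood) sorted by
    (chrom in input order, pos); a position is a C on exactly one strand, so
    the order is total.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        genome = bio.read_fasta(genome)

    frames = []
    ctx_names = np.array(["CG", "CHG", "CHH", "NA"])
    for chrom, seq in genome.items():
        if len(seq) == 0:
            continue
        arr = _normalize_sequence(seq, iupac_policy)
        n = arr.size
        padded = np.concatenate([np.full(4, _N, np.uint8), arr, np.full(4, _N, np.uint8)])

        pos_f = np.flatnonzero(arr == _C)
        pos_r = np.flatnonzero(arr == _G)

        # Forward: downstream bases are pos+1, pos+2 (N off the end).
        f1 = padded[pos_f + 5]
        f2 = padded[pos_f + 6]
        ctx_f = _context_codes(f1, f2)

        # Reverse: the C sits on the complement; its downstream bases are the
        # complements of pos-1, pos-2.
        r1 = _COMPLEMENT[padded[pos_r + 3]]
        r2 = _COMPLEMENT[padded[pos_r + 2]]
        ctx_r = _context_codes(r1, r2)

        pos = np.concatenate([pos_f, pos_r])
        strand = np.concatenate([np.zeros(pos_f.size, bool), np.ones(pos_r.size, bool)])
        ctx = np.concatenate([ctx_f, ctx_r])
        order = np.argsort(pos, kind="stable")
        pos, strand, ctx = pos[order], strand[order], ctx[order]

        if with_neighborhood:
            win = np.lib.stride_tricks.sliding_window_view(padded, 9)
            mat = win[pos].copy()
            rev = strand
            mat[rev] = _COMPLEMENT[mat[rev][:, ::-1]]
            neigh = _windows_to_strings(mat)
        else:
            neigh = ""

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": np.where(strand, "-", "+"),
                    "context": ctx_names[ctx],
                    "neighborhood": neigh,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=bio.CYTOSINE_REPORT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def context_counts(sites: pd.DataFrame) -> pd.Series:
    """Per-context site tallies (including NA)."""
    return sites["context"].value_counts().reindex(["CG", "CHG", "CHH", "NA"], fill_value=0)
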