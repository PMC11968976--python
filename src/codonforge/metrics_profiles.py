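"""Windowed codon-rarity profiles and pairwise sequence-comparison metrics.

%MinMax slides a window (default 18 codons) along a gene and scores the
balance of common and rare codons inside it; profiles of two synonymous
designs are then compared by dynamic time warping (DTW), which finds the
monotone alignment path minimizing accumulated local differences — a
shape comparison robust to local stretching. Set overlap of the codons
used (Jaccard index) and the percentage of positions carrying the exact
same codon (sequence similarity) complete the comparison suite.

Two %MinMax variants are provided because two definitions circulate:

* ``paper``     — per window, (max - min) / (max + min) x 100 of the
  codon usage frequencies observed in the window; range [0, 100].
* ``canonical`` — the Clarke-Clark formulation: the window's mean used
  frequency is compared against the means of the per-amino-acid max,
  min and average frequencies, signed by whether common or rare codons
  dominate; range [-100, 100].

Frequencies are family-relative (each codon's share within its
synonymous family), matching the rarity semantics of the w < 0.30 rule.

DTW likewise ships two conventions: ``tool_compatible`` (the symmetric2
step pattern on absolute differences, normalized by n + m, as in the
standard dtw packages) and ``paper`` (square root of summed squared
differences along the optimal monotone path).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .usage_tables import UsageTable, compute_cfd, compute_csi, compute_gc, iter_codons

MinMaxVariant = Literal["paper", "canonical"]
DTWVariant = Literal["tool_compatible", "paper"]
DEFAULT_WINDOW = 18


@dataclass(frozen=True)
class MinMaxProfile:
    values: np.ndarray
    window: int
    variant: MinMaxVariant

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DTWResult:
    distance: float
    normalized_distance: float
    path: tuple[tuple[int, int], ...]


def minmax_profile(
    dna: str,
    table: UsageTable,
    window: int = DEFAULT_WINDOW,
    variant: MinMaxVariant = "paper",
) -> MinMaxProfile:
    """Sliding-window codon-rarity profile of a codon-aligned sequence."""
    codons = iter_codons(dna)
    n = len(codons) - window + 1
    if n < 1:
        raise ValueError(f"sequence has {len(codons)} codons, shorter than window {window}")
    freq = np.array([table.freq[c] for c in codons])
    if variant == "paper":
        values = np.empty(n)
        for i in range(n):
            win = freq[i : i + window]
            hi, lo = win.max(), win.min()
            values[i] = 0.0 if hi + lo == 0 else (hi - lo) / (hi + lo) * 100.0
    elif variant == "canonical":
        fam_stats = {}
        for c in set(codons):
            aa = table.aa_of(c)
            if aa not in fam_stats:
                fam_freqs = [table.freq[x] for x in table.family(aa)]
                fam_stats[aa] = (max(fam_freqs), min(fam_freqs), sum(fam_freqs) / len(fam_freqs))
        fmax = np.array([fam_stats[table.aa_of(c)][0] for c in codons])
        fmin = np.array([fam_stats[table.aa_of(c)][1] for c in codons])
        favg = np.array([fam_stats[table.aa_of(c)][2] for c in codons])
        values = np.empty(n)
        for i in range(n):
            sl = slice(i, i + window)
            x_act, x_max, x_min, x_avg = (
                freq[sl].mean(),
                fmax[sl].mean(),
                fmin[sl].mean(),
                favg[sl].mean(),
            )
            if x_act >= x_avg:
                values[i] = 0.0 if x_max == x_avg else 100.0 * (x_act - x_avg) / (x_max - x_avg)
            else:
                values[i] = 0.0 if x_avg == x_min else -100.0 * (x_avg - x_act) / (x_avg - x_min)
    else:
        raise ValueError(f"unknown %MinMax variant {variant!r}")
    return MinMaxProfile(values=values, window=window, variant=variant)


def _check_profiles(x: MinMaxProfile, y: MinMaxProfile) -> tuple[np.ndarray, np.ndarray]:
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty profile")
    if x.window != y.window or x.variant != y.variant:
        raise ValueError("profiles must share window size and variant")
    return np.asarray(x.values, dtype=float), np.asarray(y.values, dtype=float)


def dtw_distance(
    x: MinMaxProfile, y: MinMaxProfile, variant: DTWVariant = "tool_compatible"
) -> DTWResult:
    """Dynamic-time-warping distance between two profiles.

    ``tool_compatible``: local cost |x_i - y_j|, symmetric2 step pattern
    (the diagonal move pays the cost twice), accumulated distance
    normalized by n + m. ``paper``: local cost (x_i - y_j)^2 accumulated
    over the best monotone path, distance its square root, normalized by
    the path length. Both are exact dynamic programs; the optimal path
    is returned.
    """
    xv, yv = _check_profiles(x, y)
    n, m = len(xv), len(yv)
    local = np.abs(xv[:, None] - yv[None, :])
    if variant == "paper":
        local = local**2
    elif variant != "tool_compatible":
        raise ValueError(f"unknown DTW variant {variant!r}")
    acc = np.full((n, m), np.inf)
    move = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    diag_w = 2.0 if variant == "tool_compatible" else 1.0
    acc[0, 0] = local[0, 0]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + local[i, 0]
        move[i, 0] = 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + local[0, j]
        move[0, j] = 2
    for i in range(1, n):
        row_local = local[i]
        for j in range(1, m):
            diag = acc[i - 1, j - 1] + diag_w * row_local[j]
            up = acc[i - 1, j] + row_local[j]
            left = acc[i, j - 1] + row_local[j]
            # tie-break: diagonal preferred, then up
            best, mv = diag, 0
            if up < best:
                best, mv = up, 1
            if left < best:
                best, mv = left, 2
            acc[i, j] = best
            move[i, j] = mv
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    if variant == "paper":
        distance = float(np.sqrt(acc[n - 1, m - 1]))
        normalized = distance / len(path)
    else:
        distance = float(acc[n - 1, m - 1])
        normalized = distance / (n + m)
    return DTWResult(distance=distance, normalized_distance=normalized, path=tuple(path))


def jaccard_index(dna_a: str, dna_b: str) -> float:
    """Overlap of the distinct codon sets of two sequences."""
    set_a, set_b = set(iter_codons(dna_a)), set(iter_codons(dna_b))
    if not set_a or not set_b:
        raise ValueError("empty sequence")
    return len(set_a & set_b) / len(set_a | set_b)


def sequence_similarity(dna_a: str, dna_b: str) -> float:
    """Percentage of positions where the two designs use the same codon."""
    ca, cb = iter_codons(dna_a), iter_codons(dna_b)
    if len(ca) != len(cb):
        raise ValueError(f"sequences have {len(ca)} vs {len(cb)} codons")
    if not ca:
        raise ValueError("empty sequence")
    return 100.0 * sum(a == b for a, b in zip(ca, cb)) / len(ca)


def evaluate_designs(
    designs: Mapping[str, Mapping[str, str]],
    references: Mapping[str, str],
    table: UsageTable,
    window: int = DEFAULT_WINDOW,
    minmax_variant: MinMaxVariant = "paper",
    dtw_variant: DTWVariant = "tool_compatible",
) -> dict[str, pd.DataFrame]:
    """Score several tools' designs of the same genes against references.

    ``designs`` maps tool name -> {gene id -> dna}; ``references`` maps
    gene id -> natural dna. Returns per-gene metrics (CSI, CFD, GC,
    normalized DTW / Jaccard / similarity versus the reference), a
    mean +/- sd summary per tool, and pairwise tool-vs-tool mean Jaccard
    and similarity matrices.
    """
    ref_ids = set(references)
    for tool, seqs in designs.items():
        if set(seqs) != ref_ids:
            missing = sorted(ref_ids ^ set(seqs))
            raise ValueError(f"tool {tool!r} gene ids do not match references: {missing}")
    ref_profiles = {
        gid: minmax_profile(dna, table, window, minmax_variant)
        for gid, dna in references.items()
    }
    rows = []
    for tool, seqs in designs.items():
        for gid in sorted(ref_ids):
            dna = seqs[gid]
            prof = minmax_profile(dna, table, window, minmax_variant)
            rows.append(
                {
                    "id": gid,
                    "tool": tool,
                    "CSI": compute_csi(dna, table),
                    "CFD": compute_cfd(dna, table),
                    "GC": compute_gc(dna),
                    "dtw_to_reference": dtw_distance(
                        prof, ref_profiles[gid], dtw_variant
                    ).normalized_distance,
                    "jaccard_to_reference": jaccard_index(dna, references[gid]),
                    "similarity_to_reference": sequence_similarity(dna, references[gid]),
                }
            )
    per_gene = pd.DataFrame(rows)
    summary = (
        per_gene.groupby("tool")[
            [
                "CSI",
                "CFD",
                "GC",
                "dtw_to_reference",
                "jaccard_to_reference",
                "similarity_to_reference",
            ]
        ]
        .agg(["mean", "std"])
        .sort_index()
    )
    tools = sorted(designs)
    jac = pd.DataFrame(index=tools, columns=tools, dtype=float)
    sim = pd.DataFrame(index=tools, columns=tools, dtype=float)
    for ta in tools:
        for tb in tools:
            jac.loc[ta, tb] = float(
                np.mean([jaccard_index(designs[ta][g], designs[tb][g]) for g in sorted(ref_ids)])
            )
            sim.loc[ta, tb] = float(
                np.mean(
                    [sequence_similarity(designs[ta][g], designs[tb][g]) for g in sorted(ref_ids)]
                )
            )
    return {
        "per_gene": per_gene,
        "summary": summary,
        "pairwise_jaccard": jac,
        "pairwise_similarity": sim,
    }


def write_profile_tsv(path, gene_id: str, profile: MinMaxProfile) -> None:
    """Tab-separated profile rows: id, window_start (0-based), score."""
    with open(path, "w") as handle:
        handle.write("id\twindow_start\tscore\n")
        for i, v in enumerate(profile.values):
            handle.write(f"{gene_id}\t{i}\t{v:.6g}\n")
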