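"""Quality control: spike-in rate estimation, cell gating, coverage, saturation.

The spike-in controls carry known modification states, so the pooled
modified-call fraction over a control's eligible sites estimates the
chemistry's conversion rate (on modified controls) or false-positive rate
(on the unmodified control; under CAPS+ chemistry the fully-5mC control is
also a false-positive readout, since 5mC should stay C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .calls import AlignedReadView, _aligned_positions
from .reference import (
    HMC_SPIKEIN,
    MC_SPIKEIN,
    UC_SPIKEIN,
    MethylomeTruth,
    ReferenceSet,
)


@dataclass(frozen=True)
class SpikeInClassReport:
    """Pooled proportion of modified calls over one control's eligible sites."""

    spikein_class: str
    rate: float
    n_calls: int
    ci_low: float
    ci_high: float


def _eligible_sites(
    ref: ReferenceSet, truth: MethylomeTruth
) -> dict[str, set[tuple[str, int, str]]]:
    """Truth-eligible (contig, pos0, strand) sites per spike-in class.

    mC control: its CpG cytosines (all carry 5mC); hmC control: the declared
    modified positions only; uC control: every cytosine on either strand.
    """
    spikes = ref.spikein_contigs()
    out: dict[str, set[tuple[str, int, str]]] = {}
    if MC_SPIKEIN in spikes:
        contig = spikes[MC_SPIKEIN]
        out[MC_SPIKEIN] = {
            (contig, int(p), s)
            for s in "+-"
            for p in np.flatnonzero(ref.cg_context_mask(contig, s))
        }
    if HMC_SPIKEIN in spikes:
        contig = spikes[HMC_SPIKEIN]
        out[HMC_SPIKEIN] = {
            k for k, state in truth.states.items() if k[0] == contig and state == "hmC"
        }
    if UC_SPIKEIN in spikes:
        contig = spikes[UC_SPIKEIN]
        out[UC_SPIKEIN] = {
            (contig, int(p), s) for s in "+-" for p in np.flatnonzero(ref.c_mask(contig, s))
        }
    return out


def spikein_rates(
    table: pd.DataFrame,
    ref: ReferenceSet,
    truth: MethylomeTruth,
) -> dict[str, SpikeInClassReport]:
    """Pooled conversion / false-positive rates per spike-in class.

    ``table`` must be strand-resolved (unmerged) site calls covering the
    spike-in contigs.  Each class's rate is pooled
    ``n_mod / (n_mod + n_unmod)`` over its eligible sites, with a Wilson 95%
    CI (appropriate for the near-0 false-positive rates).  Classes with zero
    calls are absent from the result, not reported as 0.
    """
    eligible = _eligible_sites(ref, truth)
    if not eligible:
        raise ValueError("reference has no spike-in contigs")
    spike_contigs = set(c for c in ref.spikein_contigs().values())
    if not table["contig"].isin(spike_contigs).any():
        raise ValueError(
            f"call table contains no spike-in contigs; expected any of {sorted(spike_contigs)}"
        )
    out = {}
    for cls, sites in eligible.items():
        if not sites:
            continue
        contig = next(iter(sites))[0]
        sub = table[table["contig"] == contig]
        if sub.empty:
            continue
        keys = list(zip(sub["contig"], sub["pos0"], sub["strand"]))
        mask = np.fromiter((k in sites for k in keys), dtype=bool, count=len(keys))
        n_mod = int(sub.loc[mask, "n_mod"].sum())
        n_unmod = int(sub.loc[mask, "n_unmod"].sum())
        n = n_mod + n_unmod
        if n == 0:
            continue
        lo, hi = proportion_confint(n_mod, n, alpha=0.05, method="wilson")
        out[cls] = SpikeInClassReport(cls, n_mod / n, n, float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# per-cell QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellQCRecord:
    cell: str
    properly_mapped_reads: int
    cpgs_covered: int
    passed: bool
    reason: str  # "", "low", or "high"


def properly_mapped_counts(reads: Sequence[AlignedReadView]) -> dict[str, int]:
    """Per-cell properly mapped read counts: MAPQ > 1, after duplicate marking."""
    counts: dict[str, int] = {}
    for r in reads:
        if r.is_unmapped or r.is_duplicate or r.mapq <= 1:
            continue
        counts[r.cell] = counts.get(r.cell, 0) + 1
    return counts


def cell_qc(
    stats: pd.DataFrame,
    min_reads: int = 500_000,
    max_reads: int = 3_000_000,
) -> list[CellQCRecord]:
    """Gate cells on properly mapped reads: pass iff min <= n <= max.

    ``stats`` needs columns ``cell`` and ``properly_mapped_reads`` (counted
    with the MAPQ > 1, post-dedup definition); ``cpgs_covered`` is carried
    through when present.
    """
    records = []
    for row in stats.itertuples(index=False):
        n = int(row.properly_mapped_reads)
        covered = int(getattr(row, "cpgs_covered", 0))
        if n < min_reads:
            passed, reason = False, "low"
        elif n > max_reads:
            passed, reason = False, "high"
        else:
            passed, reason = True, ""
        records.append(CellQCRecord(row.cell, n, covered, passed, reason))
    return records


# ---------------------------------------------------------------------------
# coverage and saturation
# ---------------------------------------------------------------------------

def _read_cpg_ids(
    read: AlignedReadView, ref: ReferenceSet, offsets: dict[str, int]
) -> np.ndarray:
    """Global merged-CpG ids covered by one read (no trimming)."""
    ap = _aligned_positions(read)
    if ap is None:
        return np.empty(0, dtype=np.int64)
    _, r = ap
    from .calls import infer_template_strand

    strand = "+" if infer_template_strand(read) == "top" else "-"
    cg = ref.cg_context_mask(read.contig, strand)
    pos = r[cg[r]]
    if strand == "-":
        pos = pos - 1  # collapse onto the top-strand C
    return offsets[read.contig] + pos


def saturation(
    reads: Sequence[AlignedReadView],
    ref: ReferenceSet,
    fractions: Sequence[float],
    seed: int = 0,
) -> list[tuple[float, int]]:
    """Distinct covered CpGs at nested read subsamples.

    Reads are permuted once (per seed); each fraction takes a prefix of that
    permutation, so smaller samples are subsets of larger ones and the curve
    is monotone by construction.  Coverage is counted on merged CpG
    dinucleotides of the genomic contigs.
    """
    fr = list(fractions)
    if any(not 0 < f <= 1 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    if sorted(fr) != fr:
        raise ValueError("fractions must be sorted ascending")
    genomic = set(ref.genomic_contigs())
    offsets: dict[str, int] = {}
    off = 0
    for c in ref.contigs:
        offsets[c] = off
        off += len(ref.contigs[c])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    seen: set[int] = set()
    cuts = [int(np.ceil(f * len(reads))) for f in fr]
    out = []
    taken = 0
    for f, cut in zip(fr, cuts):
        while taken < cut:
            read = reads[order[taken]]
            taken += 1
            if read.is_unmapped or read.contig not in genomic:
                continue
            seen.update(_read_cpg_ids(read, ref, offsets).tolist())
        out.append((f, len(seen)))
    return out


def coverage_stats(table: pd.DataFrame, ref: ReferenceSet) -> tuple[int, float]:
    """(distinct covered CpGs, fraction of the genomic merged-CpG universe).

    Expects a strand-merged CpG table; spike-in contigs are excluded from
    both numerator and denominator.
    """
    genomic = ref.genomic_contigs()
    total = sum(len(ref.cpg_dinucleotides(c)) for c in genomic)
    sub = table[table["contig"].isin(genomic)]
    covered_mask = (sub["n_mod"] + sub["n_unmod"]) > 0
    covered = int(sub.loc[covered_mask, ["contig", "pos0"]].drop_duplicates().shape[0])
    if total == 0:
        return covered, 0.0
    return covered, covered / total
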