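"""Region-level quantification: gene bodies, genomic bins, metagene profiles.

A region's modification level is the sum of modified calls divided by the
total C-or-T calls over sites falling in the region — gene bodies use the
full annotated interval, and regions with fewer than ``min_calls`` total
calls (default 5) are reported missing rather than as unreliable levels.
Chromatin-state aggregation is the same computation over a BED of labeled
intervals; it needs no separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import add_level
from .reference import GeneModel, ReferenceSet

REGION_COLUMNS = ["region_id", "cell", "n_mod", "n_total", "level"]


@dataclass(frozen=True)
class Region:
    region_id: str
    contig: str
    start0: int
    end0: int
    strand: str = "+"


def regions_from_genes(genes: Sequence[GeneModel]) -> list[Region]:
    return [Region(g.gene_id, g.contig, g.start0, g.end0, g.strand) for g in genes]


def read_bed(path: str) -> list[Region]:
    """BED intervals; column 4 (name/state label) becomes the region id."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            name = f[3] if len(f) > 3 else f"region{i + 1}"
            strand = f[5] if len(f) > 5 else "+"
            out.append(Region(name, f[0], int(f[1]), int(f[2]), strand))
    return out


def region_level(
    table: pd.DataFrame,
    regions: Sequence[Region] | Sequence[GeneModel],
    min_calls: int = 5,
    group_by: str = "cell",
    known_contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Aggregate site calls into per-region, per-cell levels.

    ``table`` is a strand-merged CpG call table.  For each region the calls
    of sites with ``start0 <= pos0 < end0`` are summed; entries with
    ``n_total < min_calls`` are omitted (missing), mirroring the exclusion
    of genes with fewer than 5 total calls.  Returns long format
    ``region_id, cell, n_mod, n_total, level``.
    """
    if regions and isinstance(regions[0], GeneModel):
        regions = regions_from_genes(regions)  # type: ignore[arg-type]
    t = table if group_by == "cell" else table.assign(cell="pooled")
    by_contig: dict[str, pd.DataFrame] = {
        c: g.sort_values("pos0") for c, g in t.groupby("contig")
    }
    rows = []
    for rg in regions:
        if known_contigs is not None and rg.contig not in known_contigs:
            import logging

            logging.getLogger(__name__).warning(
                "region %s on unknown contig %s; skipped", rg.region_id, rg.contig
            )
            continue
        sub = by_contig.get(rg.contig)
        if sub is None:
            continue
        pos = sub["pos0"].to_numpy()
        lo = np.searchsorted(pos, rg.start0, side="left")
        hi = np.searchsorted(pos, rg.end0, side="left")
        if hi <= lo:
            continue
        hits = sub.iloc[lo:hi]
        agg = hits.groupby("cell")[["n_mod", "n_unmod"]].sum()
        for cell, r in agg.iterrows():
            n_total = int(r["n_mod"] + r["n_unmod"])
            if n_total < min_calls:
                continue
            rows.append((rg.region_id, cell, int(r["n_mod"]), n_total, r["n_mod"] / n_total))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def level_matrix(region_levels: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format region levels to a cells x regions matrix (NaN = missing)."""
    return region_levels.pivot(index="cell", columns="region_id", values="level")


def bin_levels(
    table: pd.DataFrame,
    bin_size: int,
    min_calls: int = 1,
    group_by: str = "cell",
) -> pd.DataFrame:
    """Tile each contig with ``[k*b, (k+1)*b)`` bins and aggregate levels.

    Same aggregation rule as :func:`region_level`; ``min_calls`` defaults to
    1 for browser-style tracks.  Returns ``cell, contig, bin, start0, n_mod,
    n_total, level``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    t = table if group_by == "cell" else table.assign(cell="pooled")
    t = t.assign(bin=t["pos0"] // bin_size)
    agg = (
        t.groupby(["cell", "contig", "bin"], as_index=False)[["n_mod", "n_unmod"]]
        .sum()
        .rename(columns={"n_unmod": "_u"})
    )
    agg["n_total"] = agg["n_mod"] + agg["_u"]
    agg = agg[agg["n_total"] >= min_calls].drop(columns="_u")
    agg["start0"] = agg["bin"] * bin_size
    agg["level"] = agg["n_mod"] / agg["n_total"]
    return agg[["cell", "contig", "bin", "start0", "n_mod", "n_total", "level"]]


def metagene(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    body_length: int = 5000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Scale-regions metagene profile of mean site level per bin.

    Upstream and downstream flanks stay in real coordinates; each gene body
    is linearly rescaled to ``body_length``.  Minus-strand genes are
    reversed so bin 0 is always the 5' end.  Each covered site contributes
    its level once per gene; the profile is the pooled per-bin mean over
    sites across genes.  Defaults give 5000/10 = 500 bins per segment, 1500
    bins total.  Bins without any calls have NaN level.
    """
    if flank % bin_size or body_length % bin_size:
        raise ValueError("flank and body_length must be divisible by bin_size")
    n_flank = flank // bin_size
    n_body = body_length // bin_size
    n_bins = 2 * n_flank + n_body
    lv = add_level(table)
    lv = lv[(lv["n_mod"] + lv["n_unmod"]) > 0]
    by_contig = {c: g.sort_values("pos0") for c, g in lv.groupby("contig")}
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for g in genes:
        sub = by_contig.get(g.contig)
        if sub is None:
            continue
        lo_coord = g.start0 - flank
        hi_coord = g.end0 + flank
        pos = sub["pos0"].to_numpy()
        lo = np.searchsorted(pos, lo_coord, side="left")
        hi = np.searchsorted(pos, hi_coord, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        levels = sub["level"].to_numpy()[lo:hi]
        glen = g.end0 - g.start0
        bin_idx = np.empty(len(p), dtype=np.int64)
        before = p < g.start0
        after = p >= g.end0
        body = ~before & ~after
        bin_idx[before] = (p[before] - lo_coord) // bin_size
        scaled = np.floor((p[body] - g.start0) / glen * n_body).astype(np.int64)
        bin_idx[body] = n_flank + np.clip(scaled, 0, n_body - 1)
        bin_idx[after] = n_flank + n_body + (p[after] - g.end0) // bin_size
        if g.strand == "-":
            bin_idx = n_bins - 1 - bin_idx
        np.add.at(sums, bin_idx, levels)
        np.add.at(counts, bin_idx, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(n_bins), "mean_level": mean, "n_sites": counts})


def correlate(
    levels_a: pd.Series,
    levels_b: pd.Series,
) -> tuple[float, int]:
    """Pearson r between two level vectors on common non-missing entries."""
    joined = pd.concat([levels_a, levels_b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 common non-missing observations, got {n}")
    r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r), n


def write_bedgraph(tracks: pd.DataFrame, path: str, cell: str | None = None, bin_size: int | None = None) -> None:
    """Write one cell's binned levels as bedGraph."""
    t = tracks if cell is None else tracks[tracks["cell"] == cell]
    if bin_size is None:
        bin_size = int(np.gcd.reduce(np.diff(sorted(set(t["start0"]))))) if len(t) > 1 else 1
    with open(path, "w") as fh:
        for r in t.itertuples(index=False):
            fh.write(f"{r.contig}\t{r.start0}\t{r.start0 + bin_size}\t{r.level:.6g}\n")
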