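"""Direct-conversion methylation calling from alignments.

The chemistry converts *modified* cytosines so they sequence as T; the caller
therefore scores, at each reference cytosine, whether the read base is T
(modified) or C (unmodified) — on a bottom-strand template this appears as
A vs G at reference G positions. Standard filters are applied before
counting: MAPQ >= 10, duplicate removal, and exclusion of 10 bp at either
read end (conversion artefacts concentrate at fragment ends).

The library is directional (R1 reports the converted template strand), which
fixes the strand-inference rule in :func:`infer_template_strand`; that
function is the single point to change for non-directional data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import ReferenceSet

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["cell", "contig", "pos0", "strand", "context", "n_mod", "n_unmod", "n_other"]

# CIGAR op codes consumed: M=0, I=1, D=2, S=4, EQ=7, X=8
_QUERY_CONSUMING = {0, 1, 4, 7, 8}
_REF_CONSUMING = {0, 2, 7, 8}
_SUPPORTED_OPS = {0, 1, 2, 4, 7, 8}


@dataclass
class AlignedReadView:
    """Minimal view of one aligned read used by the caller."""

    name: str
    contig: str
    pos0: int
    cigar: tuple[tuple[int, int], ...]  # (op, length) pysam-style
    mapq: int
    is_reverse: bool
    is_read1: bool
    is_proper_pair: bool
    is_duplicate: bool
    seq: str
    cell: str
    is_unmapped: bool = False

    def __post_init__(self):
        qlen = sum(l for op, l in self.cigar if op in _QUERY_CONSUMING)
        if not self.is_unmapped and qlen != len(self.seq):
            raise ValueError(
                f"{self.name}: CIGAR-consumed query length {qlen} != sequence length {len(self.seq)}"
            )

    @property
    def ref_span(self) -> int:
        return sum(l for op, l in self.cigar if op in _REF_CONSUMING)


def load_sam(path: str) -> list[AlignedReadView]:
    """Read a SAM/BAM file into caller views; cell id from the CB tag."""
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cell = a.get_tag("CB") if a.has_tag("CB") else "pooled"
            out.append(
                AlignedReadView(
                    name=a.query_name,
                    contig=a.reference_name,
                    pos0=a.reference_start,
                    cigar=tuple(a.cigartuples or ()),
                    mapq=a.mapping_quality,
                    is_reverse=a.is_reverse,
                    is_read1=not a.is_read2,
                    is_proper_pair=a.is_proper_pair,
                    is_duplicate=a.is_duplicate,
                    seq=a.query_sequence,
                    cell=cell,
                )
            )
    return out


def infer_template_strand(read: AlignedReadView) -> str:
    """Which genomic strand served as the converted template.

    Directional rule: ``top`` iff (R1 and forward) or (R2 and reverse);
    ``bottom`` otherwise.  Top-strand reads are scored at reference C
    positions (C->T), bottom-strand reads at reference G positions (G->A).
    """
    if read.is_unmapped:
        raise ValueError(f"{read.name}: cannot infer template strand of unmapped read")
    if read.is_read1 != read.is_reverse:
        return "top"
    return "bottom"


# ---------------------------------------------------------------------------
# duplicate marking
# ---------------------------------------------------------------------------

def mark_duplicates(reads: Sequence[AlignedReadView]) -> list[AlignedReadView]:
    """Flag PCR duplicates per cell by fragment coordinates.

    Reads are paired by (cell, name); fragments sharing
    (cell, contig, start, end, template strand) keep one representative —
    the first by name order — and all other copies are flagged.  Marking is
    per cell: identical coordinates in different cells are distinct
    molecules.
    """
    pairs: dict[tuple[str, str], list[AlignedReadView]] = {}
    for r in reads:
        pairs.setdefault((r.cell, r.name), []).append(r)
    frag_groups: dict[tuple, list[tuple[str, list[AlignedReadView]]]] = {}
    for (cell, name), members in pairs.items():
        start = min(r.pos0 for r in members)
        end = max(r.pos0 + r.ref_span for r in members)
        strand = infer_template_strand(members[0])
        key = (cell, members[0].contig, start, end, strand)
        frag_groups.setdefault(key, []).append((name, members))
    for key, group in frag_groups.items():
        group.sort(key=lambda t: t[0])
        for name, members in group[1:]:
            for r in members:
                r.is_duplicate = True
    return list(reads)


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def _aligned_positions(read: AlignedReadView) -> tuple[np.ndarray, np.ndarray] | None:
    """(query positions, reference positions) of aligned bases, or None."""
    if len(read.cigar) == 1 and read.cigar[0][0] == 0:
        n = read.cigar[0][1]
        q = np.arange(n)
        return q, read.pos0 + q
    qs, rs = [], []
    qpos, rpos = 0, read.pos0
    for op, length in read.cigar:
        if op not in _SUPPORTED_OPS:
            logger.warning("%s: unsupported CIGAR op %d; read skipped", read.name, op)
            return None
        if op in (0, 7, 8):  # aligned
            qs.append(np.arange(qpos, qpos + length))
            rs.append(np.arange(rpos, rpos + length))
            qpos += length
            rpos += length
        elif op in (1, 4):  # insertion / soft clip: query only
            qpos += length
        elif op == 2:  # deletion: reference only
            rpos += length
    if not qs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(qs), np.concatenate(rs)


class _Accumulator:
    """Per (cell, contig, strand) dense count arrays."""

    def __init__(self):
        self.arrays: dict[tuple[str, str, str], list[np.ndarray]] = {}

    def get(self, cell: str, contig: str, strand: str, length: int) -> list[np.ndarray]:
        key = (cell, contig, strand)
        if key not in self.arrays:
            self.arrays[key] = [np.zeros(length, dtype=np.int64) for _ in range(3)]
        return self.arrays[key]


def _count_read(
    read: AlignedReadView,
    ref: ReferenceSet,
    acc: _Accumulator,
    cell_key: str,
    end_trim: int,
    contexts: frozenset[str],
    exclude_ref: np.ndarray | None,
) -> np.ndarray:
    """Accumulate one read; returns the reference positions it counted."""
    ap = _aligned_positions(read)
    if ap is None:
        return np.empty(0, dtype=int)
    q, r = ap
    qlen = len(read.seq)
    keep = (q >= end_trim) & (q < qlen - end_trim)
    q, r = q[keep], r[keep]
    if exclude_ref is not None and len(exclude_ref):
        keep = ~np.isin(r, exclude_ref)
        q, r = q[keep], r[keep]
    if len(q) == 0:
        return np.empty(0, dtype=int)
    strand = "+" if infer_template_strand(read) == "top" else "-"
    cmask = ref.c_mask(read.contig, strand)
    cgmask = ref.cg_context_mask(read.contig, strand)
    site = cmask[r]
    ctx_ok = np.zeros(len(r), dtype=bool)
    if "CG" in contexts:
        ctx_ok |= cgmask[r]
    if "CH" in contexts:
        ctx_ok |= site & ~cgmask[r]
    site &= ctx_ok
    if not site.any():
        return r
    q, rr = q[site], r[site]
    bases = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)[q]
    mod_base, unmod_base = (ord("T"), ord("C")) if strand == "+" else (ord("A"), ord("G"))
    mod, unmod, other = acc.get(cell_key, read.contig, strand, len(cmask))
    np.add.at(mod, rr[bases == mod_base], 1)
    np.add.at(unmod, rr[bases == unmod_base], 1)
    np.add.at(other, rr[(bases != mod_base) & (bases != unmod_base)], 1)
    return r


def call_sites(
    reads: Sequence[AlignedReadView],
    ref: ReferenceSet,
    min_mapq: int = 10,
    end_trim: int = 10,
    contexts: Iterable[str] = ("CG",),
    group_by: str = "cell",
    count_overlap_once: bool = True,
) -> pd.DataFrame:
    """Count modified/unmodified base calls at every covered cytosine.

    Filters: duplicate-flagged and MAPQ < ``min_mapq`` reads are excluded,
    and query positions within ``end_trim`` bases of either physical read
    end are ignored.  At each retained reference C (top template) or G
    (bottom template) in a requested context, a read base of T (resp. A)
    counts as modified, C (resp. G) as unmodified, anything else as other.
    With ``count_overlap_once`` the region where mates of a pair overlap is
    counted once, R1 preferred.

    Returns a table with one row per (cell, contig, pos0, strand) carrying
    ``n_mod``/``n_unmod``/``n_other``, sorted by (contig, pos0, strand).
    """
    contexts = frozenset(contexts)
    if not contexts <= {"CG", "CH"}:
        raise ValueError("contexts must be a subset of {'CG', 'CH'}")
    if group_by not in ("cell", "pooled"):
        raise ValueError("group_by must be 'cell' or 'pooled'")
    acc = _Accumulator()
    usable = [
        r
        for r in reads
        if not r.is_unmapped and not r.is_duplicate and r.mapq >= min_mapq
    ]
    pairs: dict[tuple[str, str], list[AlignedReadView]] = {}
    for r in usable:
        pairs.setdefault((r.cell, r.name), []).append(r)
    for (cell, name), members in sorted(pairs.items()):
        cell_key = cell if group_by == "cell" else "pooled"
        members.sort(key=lambda m: (not m.is_read1,))
        counted: np.ndarray | None = None
        for m in members:
            exclude = counted if (count_overlap_once and counted is not None) else None
            seen = _count_read(m, ref, acc, cell_key, end_trim, contexts, exclude)
            if count_overlap_once:
                counted = seen if counted is None else np.union1d(counted, seen)
    rows = []
    for (cell, contig, strand), (mod, unmod, other) in acc.arrays.items():
        covered = np.flatnonzero(mod + unmod + other)
        if len(covered) == 0:
            continue
        cg = ref.cg_context_mask(contig, strand)[covered]
        for pos, is_cg, m, u, o in zip(covered, cg, mod[covered], unmod[covered], other[covered]):
            rows.append((cell, contig, int(pos), strand, "CG" if is_cg else "CH", int(m), int(u), int(o)))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table = table.sort_values(["contig", "pos0", "strand", "cell"], kind="mergesort").reset_index(drop=True)
    return table


def merge_cpg_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse symmetric CpG calls onto the top-strand C position.

    Bottom-strand G calls at ``p`` belong to the CpG whose C sits at
    ``p - 1``; counts from the two strands are summed. Total calls are
    conserved. Only context-CG rows are accepted.
    """
    if (table["context"] != "CG").any():
        raise ValueError("merge_cpg_strands expects a context-CG table")
    t = table.copy()
    minus = t["strand"] == "-"
    t.loc[minus, "pos0"] = t.loc[minus, "pos0"] - 1
    merged = (
        t.groupby(["cell", "contig", "pos0"], as_index=False)[["n_mod", "n_unmod", "n_other"]]
        .sum()
    )
    merged["strand"] = "+"
    merged["context"] = "CG"
    merged = merged[TABLE_COLUMNS]
    return merged.sort_values(["contig", "pos0", "cell"], kind="mergesort").reset_index(drop=True)


def add_level(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``level = n_mod / (n_mod + n_unmod)`` (NaN when uncovered).

    ``n_other`` never enters the denominator: a level is the fraction of
    modified calls among C-or-T (converted-or-not) observations.
    """
    t = table.copy()
    denom = t["n_mod"] + t["n_unmod"]
    with np.errstate(invalid="ignore", divide="ignore"):
        t["level"] = np.where(denom > 0, t["n_mod"] / denom.where(denom > 0, 1), np.nan)
    return t


def write_table(table: pd.DataFrame, path: str) -> None:
    """bedMethyl-like TSV: contig, pos0, pos0+1, strand, context, counts, level."""
    t = add_level(table)
    t["end"] = t["pos0"] + 1
    cols = ["contig", "pos0", "end", "strand", "context", "n_mod", "n_unmod", "n_other", "level", "cell"]
    t[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    return t[TABLE_COLUMNS]
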