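"""Well assignment of read pairs by i5/i7 barcode.

Mirrors plate demultiplexing by read name: the simulator embeds the
``i5+i7`` tag pair in each read name, and a pair is assigned to the unique
well whose i5 AND i7 are each within ``max_mismatch`` substitutions.  With
``max_mismatch=0`` this reproduces exact name matching; tolerance is an
extension (the shipped plate's tags are pairwise Hamming >= 3, so one
mismatch is uniquely decodable).  Ambiguous pairs are never assigned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio import SeqIO

from .chemistry import CellBarcode, hamming


@dataclass
class DemuxReport:
    """Bookkeeping for one demultiplexing run; counts are conserved."""

    per_well: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    ambiguous: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.per_well.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.ambiguous


def _best_match(tag: str, candidates: Sequence[str], max_mismatch: int) -> tuple[str | None, bool]:
    """(unique best candidate within max_mismatch or None, tie flag)."""
    best: list[str] = []
    best_d = max_mismatch + 1
    for cand in candidates:
        d = hamming(tag, cand)
        if d < best_d:
            best, best_d = [cand], d
        elif d == best_d and best_d <= max_mismatch:
            best.append(cand)
    if len(best) == 1:
        return best[0], False
    return None, len(best) > 1


def assign_pair(
    i5: str,
    i7: str,
    barcodes: Sequence[CellBarcode],
    max_mismatch: int = 1,
) -> tuple[str | None, bool]:
    """Resolve a tag pair to (well or None, ambiguous flag).

    A pair is ambiguous when either tag ties between two table entries at
    its best distance within ``max_mismatch``; it is unassigned when either
    tag has no table entry within ``max_mismatch``.
    """
    m5, tie5 = _best_match(i5, sorted({b.i5 for b in barcodes}), max_mismatch)
    m7, tie7 = _best_match(i7, sorted({b.i7 for b in barcodes}), max_mismatch)
    if tie5 or tie7:
        return None, True
    if m5 is None or m7 is None:
        return None, False
    for b in barcodes:
        if b.i5 == m5 and b.i7 == m7:
            return b.well, False
    return None, False


def _parse_name_tags(name: str) -> tuple[str, str]:
    # simulator read names: pair|well|i5+i7|locus|strand
    tags = name.split("|")[2]
    i5, i7 = tags.split("+")
    return i5, i7


def demultiplex(
    r1_path: str,
    r2_path: str,
    barcodes: Sequence[CellBarcode],
    max_mismatch: int = 1,
    mode: str = "name",
    outdir: str | None = None,
) -> tuple[DemuxReport, dict[str, list]]:
    """Split a FASTQ pair into per-well pairs.

    ``mode='name'`` reads the tag pair from the read name (the simulator's
    and the plate protocol's convention); ``mode='inline'`` takes the leading
    i5 bases of R1 and i7 bases of R2 and trims them from the output reads.

    Returns the report plus a mapping well -> list of (r1_record, r2_record)
    Biopython ``SeqRecord`` pairs; if ``outdir`` is given, per-well FASTQ
    pairs are also written there as ``<well>_R1.fastq``/``<well>_R2.fastq``.
    """
    if mode not in ("name", "inline"):
        raise ValueError("mode must be 'name' or 'inline'")
    tag5_len = len(barcodes[0].i5)
    tag7_len = len(barcodes[0].i7)
    report = DemuxReport(per_well={b.well: 0 for b in barcodes})
    by_well: dict[str, list] = {b.well: [] for b in barcodes}
    it1 = SeqIO.parse(r1_path, "fastq")
    it2 = SeqIO.parse(r2_path, "fastq")
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            short = r2_path if rec2 is None else r1_path
            last = rec1 if rec1 is not None else rec2
            raise ValueError(f"R1/R2 out of sync: {short} ended before read {last.id}")
        if mode == "name":
            i5, i7 = _parse_name_tags(rec1.id)
        else:
            i5 = str(rec1.seq[:tag5_len])
            i7 = str(rec2.seq[:tag7_len])
            rec1 = rec1[tag5_len:]
            rec2 = rec2[tag7_len:]
        well, ambiguous = assign_pair(i5, i7, barcodes, max_mismatch)
        if well is None:
            if ambiguous:
                report.ambiguous += 1
            else:
                report.unassigned += 1
            continue
        report.per_well[well] += 1
        by_well[well].append((rec1, rec2))
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for well, pairs in by_well.items():
            if not pairs:
                continue
            SeqIO.write([p[0] for p in pairs], f"{outdir}/{well}_R1.fastq", "fastq")
            SeqIO.write([p[1] for p in pairs], f"{outdir}/{well}_R2.fastq", "fastq")
    return report, by_well


def write_report_tsv(report: DemuxReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("well\tn_pairs\n")
        for well, n in sorted(report.per_well.items()):
            fh.write(f"{well}\t{n}\n")
        fh.write(f"unassigned\t{report.unassigned}\n")
        fh.write(f"ambiguous\t{report.ambiguous}\n")
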