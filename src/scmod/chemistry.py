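"""Barcoded Tn5 tagmentation and direct-conversion chemistry simulation.

Models a plate-based single-cell library: per-cell Tn5 fragments carrying one
of 96 (8 i5 x 12 i7) barcode combinations, paired-end reads from either
template strand, and stochastic conversion chemistry in which a *modified*
cytosine is read as T (direct conversion — the inverse of bisulfite).

Two shipped presets encode the published per-state conversion probabilities:

* ``sctaps-paper``  — TAPS chemistry: 5mC read as T 96.6% of the time, 5hmC
  85.0%, unmodified C 0.19% (false positives).
* ``sccaps-paper``  — CAPS+ chemistry: 5hmC read as T 93.0%, 5mC 0.25%
  (5mC should stay C), unmodified C 0.38%.

On a bottom-strand template a conversion manifests as G->A relative to the
top reference strand.  The library is directional: R1 always reports the
converted template strand (see :mod:`scmod.calls` for the matching
strand-inference rule).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .reference import MethylomeTruth, ReferenceSet, STATE_UC, STATE_MC, STATE_HMC, _COMP

_T = ord("T")
_C = ord("C")
_BASE_IDX = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


@dataclass(frozen=True)
class ChemistryPreset:
    """Per-state probability that a cytosine is read as T after conversion."""

    name: str
    p_read_T_given_mC: float
    p_read_T_given_hmC: float
    p_read_T_given_uC: float
    seq_error: float = 0.001

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "name":
                continue
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def p_by_state(self) -> np.ndarray:
        """Conversion probabilities indexed by packed state (uC, mC, hmC)."""
        p = np.empty(3)
        p[STATE_UC] = self.p_read_T_given_uC
        p[STATE_MC] = self.p_read_T_given_mC
        p[STATE_HMC] = self.p_read_T_given_hmC
        return p


PRESETS = {
    "sctaps-paper": ChemistryPreset("sctaps-paper", 0.966, 0.850, 0.0019),
    "sccaps-paper": ChemistryPreset("sccaps-paper", 0.0025, 0.930, 0.0038),
}


def load_preset(name_or_path: str, seq_error: float | None = None) -> ChemistryPreset:
    """Return a shipped preset by name, or load one from a JSON file.

    A JSON preset file holds the ``ChemistryPreset`` fields. Probabilities
    outside [0, 1] are rejected.
    """
    if name_or_path in PRESETS:
        preset = PRESETS[name_or_path]
    else:
        try:
            with open(name_or_path) as fh:
                cfg = json.load(fh)
        except FileNotFoundError:
            raise ValueError(
                f"unknown preset {name_or_path!r}; available: {sorted(PRESETS)}"
            ) from None
        preset = ChemistryPreset(
            name=cfg.get("name", name_or_path),
            p_read_T_given_mC=cfg["p_read_T_given_mC"],
            p_read_T_given_hmC=cfg["p_read_T_given_hmC"],
            p_read_T_given_uC=cfg["p_read_T_given_uC"],
            seq_error=cfg.get("seq_error", 0.001),
        )
    if seq_error is not None:
        preset = dataclasses.replace(preset, seq_error=seq_error)
    return preset


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellBarcode:
    """One well of the 8 x 12 plate with its i5 (row) and i7 (column) tags."""

    well: str
    i5: str
    i7: str


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("tags must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _make_tags(n: int, length: int, min_dist: int, rng: np.random.Generator) -> list[str]:
    bases = "ACGT"
    tags: list[str] = []
    while len(tags) < n:
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, t) >= min_dist for t in tags):
            tags.append(cand)
    return tags


def make_barcode_plate(tag_length: int = 8, min_dist: int = 3, seed: int = 20240301) -> list[CellBarcode]:
    """The 96-well barcode table: 8 row i5 tags x 12 column i7 tags.

    Tags are drawn deterministically with pairwise Hamming distance >=
    ``min_dist`` within each index set, so single-substitution demultiplexing
    is uniquely decodable.
    """
    rng = np.random.default_rng(seed)
    i5s = _make_tags(8, tag_length, min_dist, rng)
    i7s = _make_tags(12, tag_length, min_dist, rng)
    plate = []
    for r, row in enumerate("ABCDEFGH"):
        for c in range(12):
            plate.append(CellBarcode(f"{row}{c + 1:02d}", i5s[r], i7s[c]))
    return plate


def write_barcode_tsv(plate: Sequence[CellBarcode], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("well\ti5\ti7\n")
        for b in plate:
            fh.write(f"{b.well}\t{b.i5}\t{b.i7}\n")


def read_barcode_tsv(path: str) -> list[CellBarcode]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            well, i5, i7 = line.split()
            out.append(CellBarcode(well, i5, i7))
    return out


# ---------------------------------------------------------------------------
# tagmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentRecord:
    """One Tn5 insert: contig interval, template strand and owning cell."""

    frag_id: int
    contig: str
    start0: int
    end0: int
    template_strand: str  # "top" | "bottom"
    cell: str


def tagment(
    ref: ReferenceSet,
    cells: Sequence[CellBarcode],
    frags_per_cell: int,
    insert_range: tuple[int, int] = (200, 700),
    spikein_fraction: float = 0.001,
    seed: int = 0,
) -> list[FragmentRecord]:
    """Draw per-cell fragments uniformly over the genome plus spike-ins.

    Each fragment lands on a spike-in contig with probability
    ``spikein_fraction`` (the controls are added at ~0.1% of library mass;
    test fixtures raise this for statistical power); within either pool the
    contig is chosen with probability proportional to its length, i.e.
    tagmentation is uniform per base.  Insert length is uniform on
    ``insert_range`` clipped to the contig; template strand is
    Bernoulli(0.5).  Deterministic per seed.
    """
    if not cells:
        raise ValueError("cell list must be non-empty")
    if not 0.0 <= spikein_fraction < 1.0:
        raise ValueError("spikein_fraction must lie in [0, 1)")
    lo, hi = insert_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid insert_range")
    rng = np.random.default_rng(seed)
    genomic = ref.genomic_contigs()
    spikes = list(ref.spikein_contigs().values())
    if spikein_fraction > 0 and not spikes:
        raise ValueError("spikein_fraction > 0 but reference has no spike-in contigs")
    glens = np.array([len(ref.contigs[c]) for c in genomic], dtype=float)
    gw = glens / glens.sum() if genomic else None
    slens = np.array([len(ref.contigs[c]) for c in spikes], dtype=float)
    sw = slens / slens.sum() if spikes else None
    frags = []
    fid = 0
    for bc in cells:
        for _ in range(frags_per_cell):
            if spikes and rng.random() < spikein_fraction:
                contig = spikes[rng.choice(len(spikes), p=sw)]
            else:
                contig = genomic[rng.choice(len(genomic), p=gw)]
            clen = len(ref.contigs[contig])
            ins = int(rng.integers(lo, hi + 1))
            ins = min(ins, clen)
            start = int(rng.integers(0, clen - ins + 1))
            strand = "top" if rng.random() < 0.5 else "bottom"
            frags.append(FragmentRecord(fid, contig, start, start + ins, strand, bc.well))
            fid += 1
    return frags


# ---------------------------------------------------------------------------
# conversion + sequencing
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    """In-memory record of one sequenced pair with its truth alignment.

    ``r1``/``r2`` are the raw read strings (5'->3' of each read).  ``r1_pos``
    and ``r2_pos`` are the 0-based leftmost reference positions; a reverse
    read's SAM SEQ is the reverse complement of the raw read.
    """

    name: str
    cell: str
    contig: str
    template_strand: str
    r1: str
    r2: str
    r1_pos: int
    r2_pos: int
    truncated: bool


def _convert_template(
    template: np.ndarray,
    states: np.ndarray,
    p_by_state: np.ndarray,
    seq_error: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply conversion chemistry then sequencing error to one template."""
    out = template.copy()
    cmask = template == _C
    if cmask.any():
        p = p_by_state[states[cmask]]
        hit = rng.random(int(cmask.sum())) < p
        idx = np.flatnonzero(cmask)[hit]
        out[idx] = _T
    if seq_error > 0:
        err = rng.random(len(out)) < seq_error
        if err.any():
            idx = np.flatnonzero(err)
            # substitute uniformly among the three alternatives
            shift = rng.integers(1, 4, size=len(idx))
            lut = np.frombuffer(b"ACGT", dtype=np.uint8)
            out[idx] = lut[(_BASE_IDX[out[idx]] + shift) % 4]
    return out


def generate_read_pairs(
    frags: Iterable[FragmentRecord],
    ref: ReferenceSet,
    truth: MethylomeTruth,
    preset: ChemistryPreset,
    read_len: int = 120,
    seed: int = 0,
    dup_frac: float = 0.0,
) -> Iterator[ReadPair]:
    """Yield converted, sequenced read pairs for each fragment.

    The template strand's sequence is taken 5'->3'; every cytosine *on the
    template* converts to T independently with the preset probability for
    its truth state, then uniform substitution errors are applied.  R1 is
    the first ``read_len`` bases of the template, R2 the reverse complement
    of the last ``read_len`` (standard FR orientation).  Fragments shorter
    than ``read_len`` give truncated, fully overlapping pairs.

    ``dup_frac`` re-emits that fraction of fragments once more (same
    coordinates, fresh error draws) to exercise duplicate marking.
    """
    rng = np.random.default_rng(seed)
    p_by_state = preset.p_by_state()
    arrays = truth.state_arrays(ref)
    emit: list[tuple[FragmentRecord, int]] = []
    for fr in frags:
        emit.append((fr, 0))
        if dup_frac > 0 and rng.random() < dup_frac:
            emit.append((fr, 1))
    for fr, copy in emit:
        seq = ref.seq_array(fr.contig)[fr.start0 : fr.end0]
        plus_states, minus_states = arrays[fr.contig]
        if fr.template_strand == "top":
            template = seq
            states = plus_states[fr.start0 : fr.end0]
        else:
            template = _COMP[seq][::-1]
            states = minus_states[fr.start0 : fr.end0][::-1]
        conv = _convert_template(template, states, p_by_state, preset.seq_error, rng)
        ins = fr.end0 - fr.start0
        rl = min(read_len, ins)
        r1_raw = conv[:rl]
        r2_raw = _COMP[conv[ins - rl :]][::-1]
        if fr.template_strand == "top":
            r1_pos = fr.start0
            r2_pos = fr.end0 - rl
        else:
            # template runs right-to-left on the reference
            r1_pos = fr.end0 - rl
            r2_pos = fr.start0
        name = f"frag{fr.frag_id}" + (f"dup{copy}" if copy else "")
        yield ReadPair(
            name=name,
            cell=fr.cell,
            contig=fr.contig,
            template_strand=fr.template_strand,
            r1=r1_raw.tobytes().decode("ascii"),
            r2=r2_raw.tobytes().decode("ascii"),
            r1_pos=r1_pos,
            r2_pos=r2_pos,
            truncated=rl < read_len,
        )


def _sam_header(ref: ReferenceSet) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.contigs.items()],
            "PG": [{"ID": "scmod", "PN": "scmod"}],
        }
    )


def _revcomp_str(s: str) -> str:
    return _COMP[np.frombuffer(s.encode(), dtype=np.uint8)][::-1].tobytes().decode()


def convert_and_sequence(
    frags: Sequence[FragmentRecord],
    ref: ReferenceSet,
    truth: MethylomeTruth,
    preset: ChemistryPreset,
    r1_path: str,
    r2_path: str,
    sam_path: str,
    barcodes: Sequence[CellBarcode] | None = None,
    read_len: int = 120,
    seed: int = 0,
    dup_frac: float = 0.0,
    inline_barcodes: bool = False,
) -> dict:
    """Write paired FASTQ plus a truth-position SAM for the given fragments.

    Read names encode ``pair-name|well|i5+i7|contig:start-end|strand`` so the
    demultiplexer can operate name-based, mirroring plate demultiplexing by
    read name; ``inline_barcodes`` additionally prepends i5 to R1 and i7 to
    R2 for in-read demultiplexing tests.  SAM records carry all-match CIGARs
    at the fragment's true coordinates, MAPQ 60, proper-pair flags and the
    cell barcode in the ``CB`` tag.
    """
    bc_by_well = {b.well: b for b in (barcodes or make_barcode_plate())}
    header = _sam_header(ref)
    tid = {c: i for i, c in enumerate(ref.contigs)}
    n_pairs = 0
    n_truncated = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, pysam.AlignmentFile(
        sam_path, "w", header=header
    ) as sam:
        for rp in generate_read_pairs(frags, ref, truth, preset, read_len, seed, dup_frac):
            bc = bc_by_well[rp.cell]
            qname = f"{rp.name}|{rp.cell}|{bc.i5}+{bc.i7}|{rp.contig}:{rp.r1_pos}|{rp.template_strand}"
            n_pairs += 1
            n_truncated += rp.truncated
            r1_seq, r2_seq = rp.r1, rp.r2
            if inline_barcodes:
                r1_seq = bc.i5 + r1_seq
                r2_seq = bc.i7 + r2_seq
            f1.write(f"@{qname}/1\n{r1_seq}\n+\n{'I' * len(r1_seq)}\n")
            f2.write(f"@{qname}/2\n{r2_seq}\n+\n{'I' * len(r2_seq)}\n")

            top = rp.template_strand == "top"
            rl1, rl2 = len(rp.r1), len(rp.r2)
            for is_r1 in (True, False):
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                raw = rp.r1 if is_r1 else rp.r2
                pos = rp.r1_pos if is_r1 else rp.r2_pos
                # R1 maps forward on a top-strand template; everything else flips
                reverse = (not top) if is_r1 else top
                a.query_sequence = _revcomp_str(raw) if reverse else raw
                a.reference_id = tid[rp.contig]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{len(raw)}M"
                flag = 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if is_r1 else 0x80
                if reverse:
                    flag |= 0x10
                else:
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = tid[rp.contig]
                a.next_reference_start = rp.r2_pos if is_r1 else rp.r1_pos
                span = max(rp.r1_pos + rl1, rp.r2_pos + rl2) - min(rp.r1_pos, rp.r2_pos)
                a.template_length = span if pos == min(rp.r1_pos, rp.r2_pos) else -span
                a.set_tag("CB", rp.cell)
                a.query_qualities = pysam.qualitystring_to_array("I" * len(raw))
                sam.write(a)
    return {"n_pairs": n_pairs, "n_truncated": n_truncated}
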