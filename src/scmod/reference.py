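"""Synthetic reference genomes, spike-in controls and ground-truth methylomes.

This module builds the coordinate frame every downstream stage works in: a
small multi-contig genome, the three spike-in controls used to estimate
conversion chemistry performance (a fully CpG-methylated 2-kb contig, a fully
unmodified 2-kb contig, and a short oligo-like contig carrying 5hmC at
declared positions), a per-cytosine modification truth map, and a simple gene
annotation used for metagene and gene-body analyses.

Coordinates are 0-based, half-open throughout.  The strand of a CpG site is
the strand of its cytosine: the top-strand C of a CpG dinucleotide at
position ``p`` is ``(contig, p, '+')`` and its bottom-strand partner is the G
at ``(contig, p+1, '-')``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# spike-in class labels
GENOMIC = "genomic"
MC_SPIKEIN = "mC_spikein"
UC_SPIKEIN = "uC_spikein"
HMC_SPIKEIN = "hmC_spikein"
SPIKEIN_CLASSES = (MC_SPIKEIN, UC_SPIKEIN, HMC_SPIKEIN)

# modification states (values used in the packed per-contig state arrays)
STATE_UC = 0
STATE_MC = 1
STATE_HMC = 2
STATE_NAMES = {STATE_UC: "uC", STATE_MC: "mC", STATE_HMC: "hmC"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def revcomp(seq: str) -> str:
    return _COMP[_seq_to_array(seq)][::-1].tobytes().decode("ascii")


@dataclass
class ReferenceSet:
    """Contig sequences plus the CpG index and spike-in labels.

    Attributes
    ----------
    contigs:
        Mapping contig name -> uppercase DNA string.
    spikein_class:
        Mapping contig name -> one of ``genomic``, ``mC_spikein``,
        ``uC_spikein``, ``hmC_spikein``.
    """

    contigs: dict[str, str]
    spikein_class: dict[str, str]
    _arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if set(self.contigs) != set(self.spikein_class):
            raise ValueError("contigs and spikein_class must have identical keys")
        for cls in SPIKEIN_CLASSES:
            n = sum(1 for v in self.spikein_class.values() if v == cls)
            if n > 1:
                raise ValueError(f"spike-in class {cls} present {n} times; at most once allowed")

    # -- array accessors -------------------------------------------------
    def seq_array(self, contig: str) -> np.ndarray:
        """The contig as a uint8 array of ASCII codes (cached)."""
        arr = self._arrays.get(contig)
        if arr is None:
            arr = _seq_to_array(self.contigs[contig])
            self._arrays[contig] = arr
        return arr

    def c_mask(self, contig: str, strand: str) -> np.ndarray:
        """Boolean mask of cytosine positions on the given strand.

        On '+' these are reference ``C`` bases; on '-' they are reference
        ``G`` bases (a G on top is a C on the bottom strand).
        """
        a = self.seq_array(contig)
        return a == (ord("C") if strand == "+" else ord("G"))

    def cg_context_mask(self, contig: str, strand: str) -> np.ndarray:
        """Mask of cytosines in CpG context on the given strand."""
        a = self.seq_array(contig)
        m = np.zeros(len(a), dtype=bool)
        if strand == "+":
            m[:-1] = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
        else:
            m[1:] = (a[1:] == ord("G")) & (a[:-1] == ord("C"))
        return m

    # -- derived indexes -------------------------------------------------
    @property
    def cpg_index(self) -> list[tuple[str, int, str]]:
        """Every cytosine in CpG context on either strand, as (contig, pos0, strand)."""
        out: list[tuple[str, int, str]] = []
        for name in self.contigs:
            plus = np.flatnonzero(self.cg_context_mask(name, "+"))
            minus = np.flatnonzero(self.cg_context_mask(name, "-"))
            merged = [(int(p), "+") for p in plus] + [(int(p), "-") for p in minus]
            merged.sort()
            out.extend((name, p, s) for p, s in merged)
        return out

    def cpg_dinucleotides(self, contig: str) -> np.ndarray:
        """Top-strand C positions of CpG dinucleotides on one contig."""
        return np.flatnonzero(self.cg_context_mask(contig, "+"))

    def genomic_contigs(self) -> list[str]:
        return [c for c, k in self.spikein_class.items() if k == GENOMIC]

    def spikein_contigs(self) -> dict[str, str]:
        """Mapping spike-in class -> contig name for present spike-ins."""
        return {k: c for c, k in self.spikein_class.items() if k != GENOMIC}

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}


@dataclass
class MethylomeTruth:
    """Per-cytosine modification state used by the simulator and as test oracle.

    ``states`` maps ``(contig, pos0, strand)`` to one of ``uC``/``mC``/``hmC``.
    Positions absent from the map are unmodified.  ``scope`` is ``shared``
    (one methylome for all cells) or ``per_cell`` with sparse per-cell
    overrides.
    """

    states: dict[tuple[str, int, str], str] = field(default_factory=dict)
    scope: str = "shared"
    cell_overrides: dict[str, dict[tuple[str, int, str], str]] | None = None

    def validate_against(self, ref: ReferenceSet) -> None:
        for (contig, pos, strand), state in self.states.items():
            if state not in STATE_CODES:
                raise ValueError(f"unknown state {state!r}")
            if contig not in ref.contigs:
                raise ValueError(f"truth contig {contig!r} not in reference")
            if not ref.c_mask(contig, strand)[pos]:
                raise ValueError(
                    f"truth position {contig}:{pos}:{strand} is not a cytosine"
                )

    def update(self, other: "MethylomeTruth") -> "MethylomeTruth":
        self.states.update(other.states)
        return self

    def state_arrays(self, ref: ReferenceSet, cell: str | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Packed (plus, minus) uint8 state arrays per contig for fast lookup."""
        out = {}
        for contig, seq in ref.contigs.items():
            out[contig] = (
                np.zeros(len(seq), dtype=np.uint8),
                np.zeros(len(seq), dtype=np.uint8),
            )
        items: Iterable = self.states.items()
        if cell is not None and self.cell_overrides and cell in self.cell_overrides:
            items = list(items) + list(self.cell_overrides[cell].items())
        for (contig, pos, strand), state in items:
            out[contig][0 if strand == "+" else 1][pos] = STATE_CODES[state]
        return out

    def fraction(self, state: str) -> float:
        """Fraction of recorded sites carrying ``state`` (uC sites are implicit)."""
        if not self.states:
            return 0.0
        n = sum(1 for s in self.states.values() if s == state)
        return n / len(self.states)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; start0 < end0, half-open. TSS/TES follow the strand."""

    gene_id: str
    contig: str
    strand: str
    start0: int
    end0: int

    def __post_init__(self):
        if self.start0 >= self.end0:
            raise ValueError(f"gene {self.gene_id}: start0 must be < end0")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start0 if self.strand == "+" else self.end0 - 1

    @property
    def tes(self) -> int:
        return self.end0 - 1 if self.strand == "+" else self.start0


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def make_reference(
    n_contigs: int,
    lengths: Sequence[int],
    gc_fraction: float = 0.5,
    seed: int = 0,
    name_prefix: str = "chr",
) -> ReferenceSet:
    """Generate a genome of ``n_contigs`` i.i.d.-base contigs at the given GC.

    Deterministic per seed. Contigs are named ``chr1``..``chrN``.
    """
    if n_contigs != len(lengths):
        raise ValueError("n_contigs must equal len(lengths)")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ])
    contigs = {}
    for i, length in enumerate(lengths, start=1):
        draws = rng.choice(_BASES, size=length, p=p)
        contigs[f"{name_prefix}{i}"] = draws.tobytes().decode("ascii")
    return ReferenceSet(contigs, {c: GENOMIC for c in contigs})


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def add_spikeins(
    ref: ReferenceSet,
    hmC_positions: Sequence[int] | None = None,
    seed: int = 0,
    mc_length: int = 2000,
    uc_length: int = 2000,
    hmc_length: int = 400,
) -> tuple[ReferenceSet, MethylomeTruth]:
    """Append the three spike-in control contigs and their truth states.

    * ``spike_mC``  — lambda-like fully CpG-methylated contig (all CpG
      cytosines on both strands carry 5mC).
    * ``spike_uC``  — fully unmodified contig; carries no truth entries.
    * ``spike_hmC`` — oligo-like contig with 5hmC only at the declared
      positions. ``hmC_positions`` default to every CpG cytosine on both
      strands; positions must fall on cytosines (C on '+' or G giving a
      bottom-strand C).
    """
    if hmc_length < 100:
        raise ValueError("hmC spike-in contig must be at least 100 bp")
    rng = np.random.default_rng(seed)
    new_contigs = dict(ref.contigs)
    new_class = dict(ref.spikein_class)
    specs = {
        "spike_mC": (MC_SPIKEIN, mc_length),
        "spike_uC": (UC_SPIKEIN, uc_length),
        "spike_hmC": (HMC_SPIKEIN, hmc_length),
    }
    for name, (cls, length) in specs.items():
        if name in new_contigs:
            raise ValueError(f"contig {name} already present")
        new_contigs[name] = _random_seq(rng, length)
        new_class[name] = cls
    out = ReferenceSet(new_contigs, new_class)

    truth = MethylomeTruth()
    # fully methylated control: every CpG cytosine, both strands
    for strand in "+-":
        for pos in np.flatnonzero(out.cg_context_mask("spike_mC", strand)):
            truth.states[("spike_mC", int(pos), strand)] = "mC"
    # hmC control: declared positions only
    hmc_arr = out.seq_array("spike_hmC")
    if hmC_positions is None:
        declared: list[tuple[int, str]] = []
        for strand in "+-":
            declared += [(int(p), strand) for p in np.flatnonzero(out.cg_context_mask("spike_hmC", strand))]
    else:
        declared = []
        for pos in hmC_positions:
            if not 0 <= pos < len(hmc_arr):
                raise ValueError(f"hmC position {pos} outside spike_hmC")
            base = chr(hmc_arr[pos])
            if base == "C":
                declared.append((pos, "+"))
            elif base == "G":
                declared.append((pos, "-"))
            else:
                raise ValueError(f"hmC position {pos} is {base}, not a cytosine on either strand")
    for pos, strand in declared:
        truth.states[("spike_hmC", pos, strand)] = "hmC"
    return out, truth


def assign_methylome(
    ref: ReferenceSet,
    global_mC: float = 0.0,
    global_hmC: float = 0.0,
    tss_dip_width: int = 2000,
    tss_dip_depth: float = 0.8,
    genes: Sequence[GeneModel] = (),
    seed: int = 0,
    symmetric: bool = True,
) -> MethylomeTruth:
    """Draw per-CpG modification states for the genomic contigs.

    Each CpG dinucleotide independently becomes 5mC with probability
    ``global_mC * f`` and 5hmC with probability ``global_hmC * f``, where
    ``f = 1 - depth * k(d)`` and ``k`` is a triangular kernel of half-width
    ``tss_dip_width`` on the distance ``d`` to the nearest TSS — emulating
    the depletion of both marks around transcription start sites.  With
    ``symmetric=True`` (default) both strands of a CpG share one state.
    CpH cytosines are left unmodified.
    """
    if global_mC < 0 or global_hmC < 0 or global_mC + global_hmC > 1:
        raise ValueError("require global_mC, global_hmC >= 0 and their sum <= 1")
    rng = np.random.default_rng(seed)
    truth = MethylomeTruth()
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    for contig in ref.genomic_contigs():
        cpos = ref.cpg_dinucleotides(contig)  # top-strand C positions
        if len(cpos) == 0:
            continue
        f = np.ones(len(cpos))
        for g in genes_by_contig.get(contig, []):
            d = np.abs(cpos - g.tss)
            kern = np.clip(1.0 - d / tss_dip_width, 0.0, None)
            f = np.minimum(f, 1.0 - tss_dip_depth * kern)
        strandsets = ([("+", "-")] if symmetric else [("+",), ("-",)])
        for strands in strandsets:
            u = rng.random(len(cpos))
            is_mc = u < global_mC * f
            is_hmc = (~is_mc) & (u < (global_mC + global_hmC) * f)
            for p in cpos[is_mc]:
                for s in strands:
                    pos = int(p) if s == "+" else int(p) + 1
                    truth.states[(contig, pos, s)] = "mC"
            for p in cpos[is_hmc]:
                for s in strands:
                    pos = int(p) if s == "+" else int(p) + 1
                    truth.states[(contig, pos, s)] = "hmC"
    return truth


def make_genes(
    ref: ReferenceSet,
    n_genes: int,
    length_range: tuple[int, int] = (5000, 20000),
    seed: int = 0,
) -> list[GeneModel]:
    """Place ``n_genes`` genes uniformly on the genomic contigs.

    Contigs are chosen with probability proportional to length; strand is
    Bernoulli(0.5).  Overlap is allowed.
    """
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid length_range")
    contigs = ref.genomic_contigs()
    lens = np.array([len(ref.contigs[c]) for c in contigs], dtype=float)
    eligible = lens >= lo
    if n_genes > 0 and not eligible.any():
        raise ValueError("length_range exceeds every genomic contig length")
    rng = np.random.default_rng(seed)
    w = np.where(eligible, lens, 0.0)
    w = w / w.sum() if n_genes else w
    genes = []
    for i in range(n_genes):
        contig = contigs[rng.choice(len(contigs), p=w)]
        clen = len(ref.contigs[contig])
        glen = int(rng.integers(lo, min(hi, clen) + 1))
        start = int(rng.integers(0, clen - glen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i + 1}", contig, strand, start, start + glen))
    return genes


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_fasta(ref: ReferenceSet, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene feature lines (GTF: 1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\tscmod\tgene\t{g.start0 + 1}\t{g.end0}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            gene_id = f[8].split('gene_id "')[1].split('"')[0]
            genes.append(GeneModel(gene_id, f[0], f[6], int(f[3]) - 1, int(f[4])))
    return genes


def write_truth_tsv(truth: MethylomeTruth, path: str) -> None:
    rows = sorted(truth.states.items())
    with open(path, "w") as fh:
        fh.write("contig\tpos0\tstrand\tstate\n")
        for (contig, pos, strand), state in rows:
            fh.write(f"{contig}\t{pos}\t{strand}\t{state}\n")


def read_truth_tsv(path: str) -> MethylomeTruth:
    df = pd.read_csv(path, sep="\t")
    truth = MethylomeTruth()
    for r in df.itertuples(index=False):
        truth.states[(r.contig, int(r.pos0), r.strand)] = r.state
    return truth
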