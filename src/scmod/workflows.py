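"""End-to-end in-memory pipelines used by the CLI, tests and reports.

These wire the simulator, caller and QC together without touching disk:
reads are generated, duplicate-marked, piled up and summarized in one call.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import calls, chemistry, qc, reference
from .calls import AlignedReadView
from .chemistry import ChemistryPreset, ReadPair


def read_views_from_pairs(pairs: Sequence[ReadPair]) -> list[AlignedReadView]:
    """Turn simulated read pairs into caller views (bypassing SAM files).

    Mirrors the SAM writer's conventions exactly: R1 maps forward on a
    top-strand template, SEQ is reference-forward oriented, MAPQ 60,
    all-match CIGAR.
    """
    from .reference import _COMP

    out = []
    for rp in pairs:
        top = rp.template_strand == "top"
        for is_r1 in (True, False):
            raw = rp.r1 if is_r1 else rp.r2
            pos = rp.r1_pos if is_r1 else rp.r2_pos
            reverse = (not top) if is_r1 else top
            seq = raw
            if reverse:
                seq = (
                    _COMP[np.frombuffer(raw.encode(), dtype=np.uint8)][::-1]
                    .tobytes()
                    .decode()
                )
            out.append(
                AlignedReadView(
                    name=rp.name,
                    contig=rp.contig,
                    pos0=pos,
                    cigar=((0, len(raw)),),
                    mapq=60,
                    is_reverse=reverse,
                    is_read1=is_r1,
                    is_proper_pair=True,
                    is_duplicate=False,
                    seq=seq,
                    cell=rp.cell,
                )
            )
    return out


def simulate_dataset(
    preset: ChemistryPreset,
    seed: int,
    n_cells: int = 4,
    frags_per_cell: int = 3000,
    spikein_fraction: float = 0.001,
    genomic_lengths: Sequence[int] = (20000,),
    global_mC: float = 0.7,
    global_hmC: float = 0.05,
    insert_range: tuple[int, int] = (200, 400),
    read_len: int = 120,
    dup_frac: float = 0.0,
    n_genes: int = 0,
    gene_length_range: tuple[int, int] = (2000, 5000),
):
    """Simulate a complete small dataset; returns (ref, truth, genes, reads).

    Sub-seeds for the reference, methylome, tagmentation and chemistry are
    derived from ``seed`` so one integer reproduces everything.
    """
    ss = np.random.SeedSequence(seed)
    s_ref, s_truth, s_genes, s_tag, s_chem = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    ref = reference.make_reference(len(genomic_lengths), list(genomic_lengths), 0.5, seed=s_ref)
    ref, spike_truth = reference.add_spikeins(ref, seed=s_ref)
    genes = (
        reference.make_genes(ref, n_genes, gene_length_range, seed=s_genes) if n_genes else []
    )
    truth = reference.assign_methylome(
        ref, global_mC=global_mC, global_hmC=global_hmC, genes=genes, seed=s_truth
    )
    truth.update(spike_truth)
    plate = chemistry.make_barcode_plate()[:n_cells]
    frags = chemistry.tagment(
        ref,
        plate,
        frags_per_cell,
        insert_range=insert_range,
        spikein_fraction=spikein_fraction,
        seed=s_tag,
    )
    pairs = list(
        chemistry.generate_read_pairs(
            frags, ref, truth, preset, read_len=read_len, seed=s_chem, dup_frac=dup_frac
        )
    )
    reads = read_views_from_pairs(pairs)
    return ref, truth, genes, frags, reads


def spikein_experiment(
    preset_name: str,
    seed: int,
    n_cells: int = 8,
    frags_per_cell: int = 8000,
    spikein_fraction: float = 0.96,
    seq_error: float = 0.0,
) -> dict:
    """Estimate spike-in conversion/false-positive rates from a simulation.

    Runs the full path — tagmentation, conversion chemistry, duplicate
    marking, site calling with the standard filters, spike-in pooling —
    and returns the per-class reports together with the generating preset.
    The spike-in fraction is raised far above the experimental ~0.1% so
    each control collects enough base calls for tight binomial estimates.
    """
    preset = chemistry.load_preset(preset_name, seq_error=seq_error)
    ref, truth, _, _, reads = simulate_dataset(
        preset,
        seed,
        n_cells=n_cells,
        frags_per_cell=frags_per_cell,
        spikein_fraction=spikein_fraction,
    )
    calls.mark_duplicates(reads)
    table = calls.call_sites(
        reads, ref, min_mapq=10, end_trim=10, contexts=("CG", "CH"), group_by="pooled"
    )
    report = qc.spikein_rates(table, ref, truth)
    return {"preset": preset, "report": report, "table": table, "ref": ref, "truth": truth}
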