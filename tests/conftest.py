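"""Shared fixtures and the independent brute-force pileup oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scmod import calls, chemistry, reference, workflows


@pytest.fixture(scope="session")
def small_ref():
    return reference.make_reference(2, [5000, 3000], 0.5, seed=11)


@pytest.fixture(scope="session")
def spiked_ref():
    ref = reference.make_reference(1, [20000], 0.5, seed=11)
    return reference.add_spikeins(ref, seed=11)


@pytest.fixture(scope="session")
def sim_dataset():
    """A small full simulation under the TAPS preset, error-free chemistry."""
    preset = chemistry.load_preset("sctaps-paper", seq_error=0.0)
    ref, truth, genes, frags, reads = workflows.simulate_dataset(
        preset, seed=7, n_cells=3, frags_per_cell=400, spikein_fraction=0.2
    )
    return {"preset": preset, "ref": ref, "truth": truth, "frags": frags, "reads": reads}


# ---------------------------------------------------------------------------
# brute-force pileup oracle: plain-python recount over read strings
# ---------------------------------------------------------------------------

def brute_force_pileup(
    reads,
    ref,
    min_mapq=10,
    end_trim=10,
    contexts=("CG",),
    group_by="cell",
    count_overlap_once=True,
):
    """Independent recount: walks every read string base by base.

    Uses only string operations and dicts; supports all-match CIGARs (the
    simulator's output). Returns a DataFrame shaped like call_sites output.
    """
    contexts = set(contexts)
    counts = {}  # (cell, contig, pos, strand) -> [mod, unmod, other]
    by_pair = {}
    for r in reads:
        if r.is_unmapped or r.is_duplicate or r.mapq < min_mapq:
            continue
        by_pair.setdefault((r.cell, r.name), []).append(r)
    for (cell, name), members in sorted(by_pair.items()):
        members = sorted(members, key=lambda m: 0 if m.is_read1 else 1)
        taken = set()
        for m in members:
            assert len(m.cigar) == 1 and m.cigar[0][0] == 0
            seq = ref.contigs[m.contig]
            if (m.is_read1 and not m.is_reverse) or (not m.is_read1 and m.is_reverse):
                strand, mod_b, unmod_b, base_b = "+", "T", "C", "C"
            else:
                strand, mod_b, unmod_b, base_b = "-", "A", "G", "G"
            n = len(m.seq)
            for q in range(n):
                if q < end_trim or q >= n - end_trim:
                    continue
                p = m.pos0 + q
                if count_overlap_once and p in taken:
                    continue
                taken.add(p)
                if seq[p] != base_b:
                    continue
                if strand == "+":
                    ctx = "CG" if p + 1 < len(seq) and seq[p + 1] == "G" else "CH"
                else:
                    ctx = "CG" if p - 1 >= 0 and seq[p - 1] == "C" else "CH"
                if ctx not in contexts:
                    continue
                key = (cell if group_by == "cell" else "pooled", m.contig, p, strand)
                c = counts.setdefault(key, [0, 0, 0])
                b = m.seq[q]
                if b == mod_b:
                    c[0] += 1
                elif b == unmod_b:
                    c[1] += 1
                else:
                    c[2] += 1
    rows = []
    for (cell, contig, pos, strand), (mod, unmod, other) in counts.items():
        seq = ref.contigs[contig]
        if strand == "+":
            ctx = "CG" if pos + 1 < len(seq) and seq[pos + 1] == "G" else "CH"
        else:
            ctx = "CG" if seq[pos - 1] == "C" else "CH"
        rows.append((cell, contig, pos, strand, ctx, mod, unmod, other))
    df = pd.DataFrame(rows, columns=calls.TABLE_COLUMNS)
    return df.sort_values(["contig", "pos0", "strand", "cell"], kind="mergesort").reset_index(
        drop=True
    )


def make_read(
    name,
    contig,
    pos0,
    seq,
    cell="A01",
    is_read1=True,
    is_reverse=False,
    mapq=60,
    is_duplicate=False,
):
    """Hand-construct an all-match caller read view."""
    return calls.AlignedReadView(
        name=name,
        contig=contig,
        pos0=pos0,
        cigar=((0, len(seq)),),
        mapq=mapq,
        is_reverse=is_reverse,
        is_read1=is_read1,
        is_proper_pair=True,
        is_duplicate=is_duplicate,
        seq=seq,
        cell=cell,
    )
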