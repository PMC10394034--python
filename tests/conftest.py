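import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cpai.core import AlignmentIndex
from cpai.simulate import SimConfig, simulate_chr_reads, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene genome with one forced pair of each orientation."""
    cfg = SimConfig(
        n_genes=40,
        seed=7,
        pair_layout=(("convergent", 800), ("tandem", 1200), ("divergent", 600)),
        expression_rate=500.0,
        with_sequence=True,
    )
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def chr_reads(small_sim):
    """Treated/control chromatin alignments plus their indexes."""
    treated = simulate_chr_reads(small_sim, "treated")
    control = simulate_chr_reads(small_sim, "control")
    return {
        "treated": treated,
        "control": control,
        "treated_idx": AlignmentIndex(treated),
        "control_idx": AlignmentIndex(control),
    }


def make_isoform_table(rows, samples):
    """Build an IsoformCountTable from (gene, pas, chrom, strand, pos,
    cls, counts-per-sample) tuples — a hand-assembly helper for
    arithmetic tests."""
    from cpai.apa import IsoformCountTable

    pas = pd.DataFrame(
        [(r[1], r[0], r[2], r[3], r[4], r[5]) for r in rows],
        columns=["pas_id", "gene_id", "chrom", "strand", "position", "location_class"],
    )
    counts = pd.DataFrame(
        [r[6] for r in rows],
        columns=samples,
        index=pd.MultiIndex.from_arrays(
            [[r[0] for r in rows], [r[1] for r in rows]], names=["gene_id", "pas_id"]
        ),
    )
    return IsoformCountTable(counts, pas)
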