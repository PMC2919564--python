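import pytest

from rrl454.panel import table1_panel
from rrl454.protocol_sim import (PanelDesign, ReadModel, SizeSelection,
                                 make_aflp_amplicons, simulate_panel,
                                 simulate_reads, size_select)


@pytest.fixture(scope="session")
def panel():
    return table1_panel()


@pytest.fixture(scope="session")
def small_sim(panel):
    """A mid-size error-free AFLP simulation shared across test modules.

    120 kb genome, 3 lines x 2 individuals, error-free reads long enough to
    usually span whole amplicons, so classification truth is unambiguous.
    """
    design = PanelDesign(genome_length=120_000, seed=7)
    genomes = simulate_panel(design, panel)
    amplicons = []
    for e in panel.entries:
        amplicons.extend(make_aflp_amplicons(genomes, e))
    retained = size_select(amplicons, SizeSelection(), 7)
    model = ReadModel(sub_rate=0.0, hp_indel_base=0.0, chimera_rate=0.0, seed=7)
    reads = simulate_reads(retained, model, 3000)
    return {
        "design": design,
        "genomes": genomes,
        "amplicons": amplicons,
        "retained": retained,
        "reads": reads,
        "truth": {r.read_id: r.truth for r in reads},
        "amp_by_id": {a.fragment_id: a for a in retained},
    }
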