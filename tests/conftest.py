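"""Shared fixtures: small chromatograms, designs, and a simulated screen."""

from __future__ import annotations

import numpy as np
import pytest

import terpscreen as ts
from terpscreen.simulate import SimulationConfig, default_design

# Independent standard-genetic-code table, hand-entered from the code wheel;
# the package's translation goes through Bio.Seq, so this stays an oracle.
CODON_TABLE = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            CODON_TABLE[_a + _b + _c] = _AAS[16 * _i + 4 * _j + _k]


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def gaussian_tic_chromatogram(peaks, sigma=0.008, dt=1.0 / 300.0, n_scans=1380,
                              well_id="W1", ion=93.0):
    """Chromatogram whose TIC is a sum of Gaussians, all signal on one ion."""
    times = (np.arange(n_scans) + 1) * dt
    tic = np.zeros(n_scans)
    for rt, area in peaks:
        tic += area * np.exp(-0.5 * ((times - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    scans = [(float(t), ({ion: float(v)} if v > 0 else {}))
             for t, v in zip(times, tic)]
    return ts.Chromatogram(well_id, scans)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def nbt_codons():
    codons, _ = ts.expand_degenerate_codon("NBT")
    return sorted(codons)


@pytest.fixture(scope="session")
def simulated_plate():
    """One 96-well plate: two 40-well libraries plus controls, default noise."""
    cfg = SimulationConfig(seed=11)
    sim = ts.simulate_screen({"lib335": 335, "lib559": 559}, 40, cfg)
    return sim


@pytest.fixture(scope="session")
def processed_plate(simulated_plate):
    """Per-well results for the simulated plate, keyed by well id."""
    sim = simulated_plate
    refs = list(sim.config.compound_table)
    layout = sim.layouts["P1"]
    return {
        wid: ts.process_well(chrom, refs, role=layout.well_assignments[wid][0])
        for wid, chrom in sim.chromatograms.items()
    }
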