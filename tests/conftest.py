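import numpy as np
import pandas as pd
import pytest

from sirmkit import synthetic as sy
from sirmkit import sirm
from sirmkit.mid import MIDVector


@pytest.fixture
def citrate_fragments():
    return sy.CITRATE_FRAGMENTS


@pytest.fixture
def zero_abundance_references():
    """Degenerate (p13c = 0) references: all mass at m+0."""
    return {
        ("citrate", mz): sirm.binomial_reference(frag, p13c=0.0)
        for mz, frag in sy.CITRATE_FRAGMENTS.items()
    }


@pytest.fixture
def simple_table():
    """Two-sample isotopologue table with known ratios and an internal standard."""
    return pd.DataFrame(
        {
            "metabolite": ["citrate", "citrate", "citrate", sy.INTERNAL_STANDARD],
            "fragment_mz": [459, 459, 459, sy.INTERNAL_STANDARD_MZ],
            "mass_shift": [0, 1, 5, 0],
            "A": [900.0, 100.0, 1000.0, 1000.0],
            "B": [9000.0, 1000.0, 10000.0, 10000.0],
        }
    )


def perturbed_mids(mids, cv, rng):
    """Multiplicative noise on MID entries, renormalized (shared test helper)."""
    out = {}
    for key, mid in mids.items():
        noisy = mid.masses * rng.lognormal(0.0, cv, mid.masses.size)
        out[key] = MIDVector.from_intensities(noisy)
    return out


def all_tracer_mids(fractions):
    """Simulated citrate MIDs for all three tracers, keyed (tracer, mz)."""
    obs = {}
    for tracer in (sy.Tracer.U13C6_GLUCOSE, sy.Tracer.U13C5_GLUTAMINE, sy.Tracer.C13_BICARBONATE):
        for mz, mid in sy.simulate_citrate_mids(fractions, tracer).items():
            obs[(tracer, mz)] = mid
    return obs
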