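import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mitofam.reference import load_reference, gene_table, MaskedRegions
from mitofam.simulate import SimulationConfig, simulate_families


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def annotation():
    return gene_table()


@pytest.fixture(scope="session")
def masks():
    return MaskedRegions()


@pytest.fixture(scope="session")
def small_study():
    """A 30-quartet cohort reused by read-only tests."""
    return simulate_families(SimulationConfig(n_families=30, seed=7))


@pytest.fixture(scope="session")
def dyad_study():
    return simulate_families(SimulationConfig(n_families=40, design="dyad",
                                              seed=7))


def make_pileup(reference, variants=(), depth=2000, baq=33.0,
                frac_baq30=0.92, seed=0, positions=None):
    """Deterministic hand-built pileup: exact counts, no sampling noise.

    ``variants``: iterable of (pos, alt, vaf).  Counts are split evenly by
    strand with the remainder on the forward strand.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = sorted({p for p, _, _ in variants}) or [100]
    var = {p: (a, v) for p, a, v in variants}
    rows = []
    for pos in positions:
        refb = reference.base(pos)
        counts = {b: 0 for b in "ACGT"}
        alt, vaf = var.get(pos, (None, 0.0))
        k = int(round(depth * vaf)) if alt else 0
        counts[refb] = depth - k
        if alt:
            counts[alt] = k
        row = {"pos": pos, "ref": refb}
        for b in "ACGT":
            row[f"{b}_fwd"] = counts[b] - counts[b] // 2
            row[f"{b}_rev"] = counts[b] // 2
            row[f"baq_{b}"] = baq
        row["frac_baq30"] = frac_baq30
        rows.append(row)
    df = pd.DataFrame(rows)
    df["source"] = "wgs"
    return df
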