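import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from herbomirror.chrom import Chromatogram
from herbomirror.synth import ExprDesign, SyntheticDesign, generate_chromatograms, generate_probe_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_peak_trace():
    """One noise-free Gaussian peak on a flat baseline."""
    rt = np.linspace(0, 10, 500)
    y = 50.0 * np.exp(-0.5 * ((rt - 4.0) / 0.15) ** 2)
    return Chromatogram(rt, y, "clean", "synthetic")


@pytest.fixture
def default_chrom_set():
    design = SyntheticDesign(seed=7)
    chroms, truth = generate_chromatograms(design)
    return design, chroms, truth


@pytest.fixture
def small_expr_set():
    design = ExprDesign(n_probesets=60, seed=7)
    probes, pmap, truth = generate_probe_arrays(design)
    return design, probes, pmap, truth
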