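import numpy as np
import pytest

from chirospec import (MILLIDEGREES, SampleInfo, Spectrum, calibration)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def sample_info():
    """Typical far-UV acquisition: 20 µM protein, 0.1 cm path, 70 peptide bonds."""
    return SampleInfo(protein_conc=20e-6, pathlength=0.1, n_bonds=70)


def random_spectrum(rng, n=51, lo=200.0, hi=250.0, unit=MILLIDEGREES):
    grid = np.linspace(lo, hi, n)
    return Spectrum(grid, rng.normal(0.0, 5.0, n), unit)


@pytest.fixture
def far_uv_mdeg(sample_info):
    """Synthetic far-UV scan in millidegrees whose mean-residue ellipticity
    shows the helical band pattern: positive maximum near 192 nm, negative
    bands near 204 and 222 nm."""
    grid = np.arange(185.0, 251.0)
    mre = (9000.0 * np.exp(-0.5 * ((grid - 192.0) / 4.0) ** 2)
           - 11000.0 * np.exp(-0.5 * ((grid - 204.0) / 5.0) ** 2)
           - 9000.0 * np.exp(-0.5 * ((grid - 222.0) / 7.0) ** 2))
    from chirospec import MEAN_RESIDUE_ELLIPTICITY
    s = Spectrum(grid, mre, MEAN_RESIDUE_ELLIPTICITY)
    return calibration.to_millidegrees(s, sample_info)
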