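import numpy as np
import pytest

from enrichms import Peptide, Run, SpectrumScan
from enrichms.simulate import SimConfig, simulate_run


@pytest.fixture
def reference_peptide() -> Peptide:
    """The 134-143 tryptic peptide of the ATP synthase beta subunit."""
    return Peptide("IPVGPETLGR", protein_start=134)


@pytest.fixture
def noise_free_run():
    """Noise-free simulated run at 0.482% true enrichment."""
    return simulate_run(SimConfig(true_enrichment=0.00482))


def make_gaussian_xic(amplitude=1000.0, center=10.0, sigma=0.1, step=0.005,
                      halfwidth=6.0):
    """Densely sampled Gaussian XIC for integration tests."""
    from enrichms.msdata import XIC

    t = np.arange(center - halfwidth * sigma, center + halfwidth * sigma + step,
                  step)
    y = amplitude * np.exp(-((t - center) ** 2) / (2 * sigma**2))
    return XIC(target_mz=500.0, tolerance=0.5, times=t, intensities=y)


@pytest.fixture
def gaussian_xic():
    return make_gaussian_xic()


def make_run(peak_lists, rts=None, precursor=1000.0):
    """Small hand-built run: peak_lists is a list of per-scan peak lists."""
    rts = rts or [float(i) for i in range(len(peak_lists))]
    scans = [
        SpectrumScan(retention_time=rt, precursor_target_mz=precursor,
                     peaks=list(peaks))
        for rt, peaks in zip(rts, peak_lists)
    ]
    return Run(scans=scans)
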