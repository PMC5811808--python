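import numpy as np
import pytest

from tracernmr import (
    AcquisitionParams,
    CarbonSite,
    Isotopomer,
    IsotopomerMixture,
    SpinSystemTemplate,
    alanine_template,
    glucose_c6_template,
)


@pytest.fixture
def alanine():
    return alanine_template()


@pytest.fixture
def glucose():
    return glucose_c6_template()


@pytest.fixture
def two_spin():
    """Minimal two-carbon system with a single 35 Hz coupling."""
    return SpinSystemTemplate(
        "two-spin",
        carbons=(
            CarbonSite(site_id=1, carbon_shift=0.0, proton_shift=1.0,
                       n_attached_protons=1),
            CarbonSite(site_id=2, carbon_shift=10.0, proton_shift=1.0,
                       n_attached_protons=1),
        ),
        j_cc={(1, 2): 35.0},
    )


@pytest.fixture
def narrow_acq():
    """High-resolution acquisition: 0.5 Hz grid, ~1 Hz linewidth."""
    return AcquisitionParams(
        spectral_width=2048.0,
        n_points=4096,
        r2=np.pi,
        carrier=0.0,
        field_mhz=1.0,
        zero_fill_factor=1,
    )


def iso_for(template, carbons=(), nitrogens=()):
    return Isotopomer(
        {s: s in carbons for s in template.carbon_ids},
        {s: s in nitrogens for s in template.nitrogen_ids},
    )


def unit_mixture(template, carbons=(), nitrogens=()):
    return IsotopomerMixture(((iso_for(template, carbons, nitrogens), 1.0),))
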