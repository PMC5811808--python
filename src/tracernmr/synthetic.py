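"""Synthetic study data with known ground truth.

Everything the simulator and the fitters consume can be generated here:
fixture spin systems for the metabolites of a tracer perfusion study
(glucose, alanine, lactate), noisy multiplet traces, paired isotope-filter
spectra, and enhancement series — all seeded and reproducible, with the
ground-truth mixture serialised next to every data set.

Noise enters in the time domain (complex Gaussian on the FID, which is how
spectrometer noise enters a real acquisition) before the Fourier transform.
Signal-to-noise is quoted in the conventional sense of tallest peak height
over baseline RMS.  The default noise levels target an SNR of ≈300,
representative of a short splitting-enhanced acquisition; chemical shifts
and coupling constants are literature-typical values for the fixture
metabolites and are plain data — edit them to match a calibrated system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quant_filter import FilterPair, attenuation_factor
from .simulate import (
    AcquisitionParams,
    carbon_fid,
    fid_to_spectrum,
    with_enhancement,
)
from .spectra import Spectrum1D, save_spectrum
from .spin_systems import (
    CarbonSite,
    Isotopomer,
    IsotopomerMixture,
    NitrogenSite,
    SpinSystemTemplate,
    ValidationError,
    mixture_to_dict,
    template_to_dict,
)

__all__ = [
    "NoiseSpec",
    "FixtureCase",
    "fixture_library",
    "make_noisy_trace",
    "make_filter_pair",
    "estimate_snr",
    "alanine_template",
    "glucose_c6_template",
    "lactate_template",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Time-domain complex Gaussian noise: std per point, plus the seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("noise sigma must be ≥ 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Fixture spin systems (shifts/couplings are typical literature magnitudes)
# ---------------------------------------------------------------------------


def alanine_template(j_cn_c2: float = 5.5) -> SpinSystemTemplate:
    """Full alanine spin system (C1 carboxyl, C2/Hα, C3 methyl, amine N).

    ¹J(C2,C3) = 34.9 Hz, ¹J(C1,C2) = 54 Hz; the carboxyl C1 carries no
    proton and so never gives a direct HSQC signal.  The one-bond C2–N
    coupling defaults to 5.5 Hz and the two-bond C3–N coupling is
    negligible (0).  Pass ``j_cn_c2=0`` for a variant whose C–N coupling
    is unresolvably small.
    """
    return SpinSystemTemplate(
        name="alanine" if j_cn_c2 else "alanine (unresolved C-N)",
        carbons=(
            CarbonSite(site_id=1, carbon_shift=176.6, proton_shift=0.0,
                       n_attached_protons=0),
            CarbonSite(site_id=2, carbon_shift=53.2, proton_shift=3.77,
                       n_attached_protons=1),
            CarbonSite(site_id=3, carbon_shift=18.8, proton_shift=1.47,
                       n_attached_protons=3),
        ),
        nitrogens=(NitrogenSite(site_id="N", nitrogen_shift=38.0,
                                j_hn_long_range=3.0),),
        j_cc={(2, 3): 34.9, (1, 2): 54.0},
        j_cn={(2, "N"): j_cn_c2, (3, "N"): 0.0},
    )


def glucose_c6_template() -> SpinSystemTemplate:
    """Glucose C4–C6 fragment observed at C6.

    ¹J(C5,C6) = 43 Hz, ¹J(C4,C5) = 40 Hz, and the long-range C4–C6
    coupling of 4 Hz that only becomes resolved under splitting
    enhancement.
    """
    return SpinSystemTemplate(
        name="glucose-C6",
        carbons=(
            CarbonSite(site_id=4, carbon_shift=70.5, proton_shift=3.40,
                       n_attached_protons=1),
            CarbonSite(site_id=5, carbon_shift=72.3, proton_shift=3.45,
                       n_attached_protons=1),
            CarbonSite(site_id=6, carbon_shift=63.2, proton_shift=3.72,
                       n_attached_protons=2),
        ),
        j_cc={(5, 6): 43.0, (4, 5): 40.0, (4, 6): 4.0},
    )


def lactate_template() -> SpinSystemTemplate:
    """Lactate C2/C3 fragment; ¹J(C2,C3) = 37 Hz."""
    return SpinSystemTemplate(
        name="lactate",
        carbons=(
            CarbonSite(site_id=2, carbon_shift=69.3, proton_shift=4.11,
                       n_attached_protons=1),
            CarbonSite(site_id=3, carbon_shift=22.9, proton_shift=1.32,
                       n_attached_protons=3),
        ),
        j_cc={(2, 3): 37.0},
    )


def _iso(template: SpinSystemTemplate, carbons: tuple[int, ...] = (),
         nitrogens: tuple[str, ...] = ()) -> Isotopomer:
    return Isotopomer(
        {s: s in carbons for s in template.carbon_ids},
        {s: s in nitrogens for s in template.nitrogen_ids},
    )


@dataclass
class FixtureCase:
    """A named synthetic study case with ground truth attached.

    ``nh_components`` is set only for the long-range ¹H,¹⁵N case: explicit
    (template, isotopomer, fraction) species triples, because one
    sub-population there carries an unresolvably small C–N coupling and so
    needs its own coupling-table variant.
    """

    name: str
    template: SpinSystemTemplate
    mixture: IsotopomerMixture
    observed_site: int
    acq: AcquisitionParams
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    nh_components: list[tuple[SpinSystemTemplate, Isotopomer, float]] | None = None

    def truth(self) -> dict[str, float]:
        return {
            iso.name(self.template): 100.0 * f for iso, f in self.mixture
        }


# Default indirect-dimension acquisition for the fixtures: 160 ppm of 13C
# at a 600 MHz magnet (150.9 MHz 13C), 8192 complex points before any
# enhancement-matched reduction, ~1 Hz-scale linewidth.
def _default_c13_acq(carrier: float, n_points: int = 8192) -> AcquisitionParams:
    return AcquisitionParams(
        spectral_width=160.0 * 150.9,
        n_points=n_points,
        r2=3.0,
        carrier=carrier,
        field_mhz=150.9,
        zero_fill_factor=2,
    )


def _sigma_for_snr(peak_height: float, acq: AcquisitionParams,
                   target_snr: float) -> float:
    # frequency-domain real-part noise std from n time-domain complex
    # samples of std sigma is sigma·dw·sqrt(n); solve for sigma given the
    # noiseless spectrum's tallest peak
    return peak_height / (target_snr * acq.dwell * np.sqrt(acq.n_points))


def fixture_library() -> list[FixtureCase]:
    """The shipped synthetic study cases.

    - ``fig4_glucoseC6``: glucose C6 multiplet, truth 6.8 / 41.2 / 52.0 %
      for [6-13C] / [5,6-13C] / [U-13C].
    - ``fig5_alanineC3``: alanine C3 methyl, truth 12.1 / 87.9 % for
      [3-13C] / [2,3-13C].
    - ``fig7_alanine_NH``: three equal alanine species for the long-range
      ¹H,¹⁵N experiment — ¹⁵N with unlabelled carbon, ¹³C/¹⁵N with a
      resolvable ¹J_CN, and ¹³C/¹⁵N with an unresolvably small C–N
      coupling — together giving the characteristic seven-component 2D
      multiplet.
    - ``fig2_filter_lactate``: lactate methyl filter pair with 40 %
      ground-truth ¹³C incorporation.
    """
    cases: list[FixtureCase] = []

    glc = glucose_c6_template()
    glc_mix = IsotopomerMixture((
        (_iso(glc, carbons=(6,)), 0.068),
        (_iso(glc, carbons=(5, 6)), 0.412),
        (_iso(glc, carbons=(4, 5, 6)), 0.520),
    ))
    acq_glc = _default_c13_acq(carrier=63.2)
    # target SNR ≈ 820 for the non-enhanced trace, representative of a
    # full-length acquisition; enhanced/shortened traces land lower
    peak_glc = fid_to_spectrum(
        carbon_fid(glc, glc_mix, 6, acq_glc), acq_glc
    ).intensity.max()
    cases.append(
        FixtureCase(
            name="fig4_glucoseC6",
            template=glc,
            mixture=glc_mix,
            observed_site=6,
            acq=acq_glc,
            noise=NoiseSpec(sigma=_sigma_for_snr(peak_glc, acq_glc, 820.0), seed=2024),
        )
    )

    ala = alanine_template()
    ala_mix = IsotopomerMixture((
        (_iso(ala, carbons=(3,)), 0.121),
        (_iso(ala, carbons=(2, 3)), 0.879),
    ))
    acq_ala = _default_c13_acq(carrier=18.8)
    peak_ala = fid_to_spectrum(
        carbon_fid(ala, ala_mix, 3, acq_ala), acq_ala
    ).intensity.max()
    cases.append(
        FixtureCase(
            name="fig5_alanineC3",
            template=ala,
            mixture=ala_mix,
            observed_site=3,
            acq=acq_ala,
            noise=NoiseSpec(sigma=_sigma_for_snr(peak_ala, acq_ala, 820.0), seed=2025),
        )
    )

    ala_nojcn = alanine_template(j_cn_c2=0.0)
    nh_components = [
        (ala, _iso(ala, nitrogens=("N",)), 1.0 / 3.0),
        (ala, _iso(ala, carbons=(1, 2, 3), nitrogens=("N",)), 1.0 / 3.0),
        (ala_nojcn, _iso(ala_nojcn, carbons=(1, 2, 3), nitrogens=("N",)), 1.0 / 3.0),
    ]
    nh_mix = IsotopomerMixture((
        (_iso(ala, nitrogens=("N",)), 1.0 / 3.0),
        (_iso(ala, carbons=(1, 2, 3), nitrogens=("N",)), 2.0 / 3.0),
    ))
    # r2 chosen so the interferogram decays to <1% within the sampled
    # window; weaker decay leaves truncation sidelobes that a peak counter
    # would miscount as components
    acq_nh = AcquisitionParams(
        spectral_width=40.0 * 60.8,  # 40 ppm of 15N at 60.8 MHz
        n_points=1024,
        r2=12.0,
        carrier=38.0,
        field_mhz=60.8,
        k_cn=3,
        zero_fill_factor=2,
    )
    cases.append(
        FixtureCase(
            name="fig7_alanine_NH",
            template=ala,
            mixture=nh_mix,
            observed_site=2,
            acq=acq_nh,
            noise=NoiseSpec(sigma=0.0, seed=2026),
            nh_components=nh_components,
        )
    )

    lac = lactate_template()
    lac_mix = IsotopomerMixture((
        (_iso(lac, carbons=(3,)), 0.40),
        (_iso(lac), 0.60),
    ))
    acq_lac_h = AcquisitionParams(
        spectral_width=13.0 * 600.0,  # 13 ppm of 1H at 600 MHz
        n_points=4096,
        r2=3.0,
        carrier=4.7,
        field_mhz=600.0,
        zero_fill_factor=2,
    )
    # target SNR ≈ 330 on the all-proton spectrum, typical of a short
    # quantitative 1D acquisition; the peak carries 60% (the unlabelled
    # fraction) of the unit amplitude at its centre
    t_lac = acq_lac_h.times()
    fid_lac = 0.6 * np.exp(-acq_lac_h.r2 * t_lac) * np.exp(
        2j * np.pi * (1.32 - acq_lac_h.carrier) * acq_lac_h.field_mhz * t_lac
    )
    peak_lac = fid_to_spectrum(fid_lac, acq_lac_h, "1H").intensity.max()
    cases.append(
        FixtureCase(
            name="fig2_filter_lactate",
            template=lac,
            mixture=lac_mix,
            observed_site=3,
            acq=acq_lac_h,
            noise=NoiseSpec(sigma=_sigma_for_snr(peak_lac, acq_lac_h, 330.0), seed=2027),
        )
    )
    return cases


def get_fixture(name: str) -> FixtureCase:
    for case in fixture_library():
        if case.name == name:
            return case
    raise KeyError(f"no fixture named {name!r}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_noisy_trace(
    case: FixtureCase, k_cc: int = 0, k_cn: int | None = None
) -> tuple[Spectrum1D, dict]:
    """Simulate the case's ¹³C trace and add seeded time-domain noise.

    Returns the spectrum and a truth sidecar (JSON-serialisable) recording
    the template, mixture and noise parameters.  ``sigma = 0`` reproduces
    the deterministic simulator output exactly.
    """
    acq = with_enhancement(case.acq, k_cc=k_cc, k_cn=k_cn)
    fid = carbon_fid(case.template, case.mixture, case.observed_site, acq)
    if case.noise.sigma > 0:
        rng = case.noise.rng()
        fid = fid + case.noise.sigma * (
            rng.standard_normal(acq.n_points)
            + 1j * rng.standard_normal(acq.n_points)
        )
    spectrum = fid_to_spectrum(fid, acq)
    sidecar = {
        "case": case.name,
        "template": template_to_dict(case.template),
        "truth": mixture_to_dict(case.mixture, case.template),
        "observed_site": case.observed_site,
        "k_cc": acq.k_cc,
        "k_cn": acq.k_cn,
        "noise_sigma": case.noise.sigma,
        "noise_seed": case.noise.seed,
    }
    return spectrum, sidecar


def make_filter_pair(
    case: FixtureCase,
    percent_13c: float = 40.0,
    j_ch_actual: float = 145.0,
    delta: float = 1.0 / (4.0 * 145.0),
    noise: NoiseSpec | None = None,
) -> tuple[FilterPair, dict]:
    """Paired all-¹H / ¹³C-bound-¹H spectra with known incorporation.

    The all-proton spectrum carries the full peak (¹²C centre plus ¹³C
    satellites at the labelled fraction); the filtered spectrum carries
    only the labelled fraction, scaled by the sin²(2πδJ) filter
    transmission and ¹³C-decoupled (satellites collapsed to the centre).
    """
    if not 0.0 <= percent_13c <= 100.0:
        raise ValidationError("percent_13c must be in [0, 100]")
    frac = percent_13c / 100.0
    noise = noise if noise is not None else case.noise
    site = case.template.carbon(case.observed_site)
    acq = case.acq
    t = acq.times()
    omega = (site.proton_shift - acq.carrier) * acq.field_mhz
    base = np.exp(2j * np.pi * omega * t) * np.exp(-acq.r2 * t)
    fid_all = (1.0 - frac) * base + frac * base * np.cos(np.pi * j_ch_actual * t)
    factor = attenuation_factor(j_ch_actual, delta)
    fid_filt = frac * factor * base  # decoupled: single line at the centre
    if noise.sigma > 0:
        rng = noise.rng()
        n = acq.n_points
        fid_all = fid_all + noise.sigma * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)
        )
        fid_filt = fid_filt + noise.sigma * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)
        )
    pair = FilterPair(
        spectrum_all=fid_to_spectrum(fid_all, acq, nucleus="1H"),
        spectrum_filtered=fid_to_spectrum(fid_filt, acq, nucleus="1H"),
        delta=delta,
        j_ch_nominal=1.0 / (4.0 * delta),
    )
    sidecar = {
        "case": case.name,
        "truth_percent_13c": percent_13c,
        "j_ch_actual": j_ch_actual,
        "delta": delta,
        "attenuation_factor": factor,
        "noise_sigma": noise.sigma,
        "noise_seed": noise.seed,
    }
    return pair, sidecar


def make_nh2d(
    case: FixtureCase, acq_f2: AcquisitionParams | None = None
):
    """Simulate a case's long-range ¹H,¹⁵N 2D multiplet.

    ``case.acq`` drives the ¹⁵N (F1) dimension; the proton (F2) dimension
    defaults to a narrow window around Hα at a 600 MHz magnet.
    """
    from .simulate import simulate_nh2d_components

    if case.nh_components is None:
        raise ValidationError(f"case {case.name!r} has no ¹⁵N species components")
    if acq_f2 is None:
        acq_f2 = AcquisitionParams(
            spectral_width=2.0 * 600.0,  # 2 ppm of 1H around Halpha
            n_points=1024,
            r2=6.0,
            carrier=3.77,
            field_mhz=600.0,
            zero_fill_factor=2,
        )
    return simulate_nh2d_components(case.nh_components, case.acq, acq_f2)


def estimate_snr(
    spectrum: Spectrum1D, signal_free_ppm: tuple[float, float]
) -> float:
    """Tallest peak height over baseline RMS in a signal-free window."""
    ppm = spectrum.ppm
    mask = (ppm >= signal_free_ppm[0]) & (ppm <= signal_free_ppm[1])
    if mask.sum() < 8:
        raise ValidationError("signal-free region covers too few points")
    seg = spectrum.intensity[mask]
    rms = float(np.sqrt(np.mean((seg - seg.mean()) ** 2)))
    if rms == 0.0:
        return float("inf")
    return float(spectrum.intensity.max() / rms)


def write_fixture_tree(out_dir: str | Path, k_cc: int = 0) -> list[Path]:
    """Write every fixture as native-container spectra + truth sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for case in fixture_library():
        case_dir = out_dir / case.name
        case_dir.mkdir(exist_ok=True)
        if case.name == "fig2_filter_lactate":
            pair, sidecar = make_filter_pair(case)
            for tag, spec in (("all", pair.spectrum_all),
                              ("filtered", pair.spectrum_filtered)):
                written.extend(save_spectrum(spec, case_dir / f"{tag}"))
        else:
            spectrum, sidecar = make_noisy_trace(case, k_cc=k_cc)
            written.extend(save_spectrum(spectrum, case_dir / "trace"))
        truth_path = case_dir / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        written.append(truth_path)
    return written
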