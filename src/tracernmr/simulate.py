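"""Weak-coupling simulation of splitting-enhanced HSQC multiplets.

The indirect (¹³C or ¹⁵N) dimension of the experiment is modelled as a
free-induction decay acquired after a spin echo that refocuses chemical
shift and heteronuclear ¹H couplings but lets the homonuclear C–C (and,
with a simultaneous ¹⁵N π pulse, the C–N) couplings evolve for extra
periods.  Because the extra echo delays are integer multiples ``k`` of the
dwell time, every coupling J appears in the transformed spectrum with an
apparent splitting ``(1+k)·J`` while the chemical-shift position is
unchanged.

Under the weak-coupling approximation each active coupling contributes a
``cos(π J E t)`` modulation, so a site's signal is

    s(t) = Σ_isotopomers  f · exp(i 2π Ω t) · Π_j cos(π J_j E t) · exp(−R₂ t)

with f the isotopomer fraction, Ω the offset of the observed carbon from
the carrier, and the product running over coupled sites that carry an NMR-
active label in that isotopomer.  Only isotopomers with ¹³C at the observed
site contribute at all (the one-bond transfer is the implicit ¹²C filter),
and proton-less carbons never give a direct cross peak.

The simulator is deterministic; noise belongs to :mod:`tracernmr.synthetic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .spectra import Axis, Spectrum1D, Spectrum2D
from .spin_systems import (
    Isotopomer,
    IsotopomerMixture,
    SpinSystemTemplate,
    ValidationError,
)

__all__ = [
    "AcquisitionParams",
    "apparent_splitting",
    "carbon_fid",
    "fid_to_spectrum",
    "simulate_carbon_trace",
    "simulate_satellite_spectrum",
    "apply_species_filter",
    "simulate_long_range_nh_2d",
    "simulate_nh2d_components",
    "count_components",
    "pick_peaks_1d",
    "measure_splitting",
]

NATURAL_ABUNDANCE_13C = 0.0107


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling and processing parameters of the simulated dimension.

    Parameters
    ----------
    spectral_width
        Hz; the dwell time is ``1/spectral_width``.
    n_points
        Complex points sampled before zero filling (≥ 64).
    r2
        Decay rate in s⁻¹; the absorptive Lorentzian FWHM is ``r2/π`` Hz.
    carrier
        Carrier position in ppm (centre of the spectrum).
    field_mhz
        Spectrometer frequency of the simulated nucleus in MHz, used for
        the ppm↔Hz conversion (e.g. ≈150.9 for ¹³C at a 600 MHz magnet).
    k_cc, k_cn
        Extra spin-echo increments per t₁ increment for C–C and C–N
        couplings; the apparent splittings are scaled by ``1 + k``.
        Non-negative integers because the echo delays are multiples of
        the dwell time.
    zero_fill_factor
        Total length after zero filling = ``n_points × zero_fill_factor``.
    dispersive_fraction
        Lineshape admixture in [0, 1]; 0 gives a pure absorptive
        Lorentzian, small positive values emulate the predictable
        lineshape perturbation of echo/anti-echo quadrature detection.
    """

    spectral_width: float
    n_points: int = 1024
    r2: float = 3.0
    carrier: float = 0.0
    field_mhz: float = 150.9
    k_cc: int = 0
    k_cn: int = 0
    zero_fill_factor: int = 2
    dispersive_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.spectral_width <= 0:
            raise ValidationError("spectral_width must be > 0")
        if self.n_points < 64:
            raise ValidationError("n_points must be ≥ 64")
        for name in ("k_cc", "k_cn"):
            k = getattr(self, name)
            if not (isinstance(k, (int, np.integer)) and k >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {k!r}")
        if self.zero_fill_factor < 1:
            raise ValidationError("zero_fill_factor must be ≥ 1")
        if not 0.0 <= self.dispersive_fraction <= 1.0:
            raise ValidationError("dispersive_fraction must be in [0, 1]")
        if self.r2 <= 0:
            raise ValidationError("r2 must be > 0")

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width

    @property
    def e_cc(self) -> int:
        """Apparent C–C splitting multiplier, 1 + k_cc."""
        return 1 + self.k_cc

    @property
    def e_cn(self) -> int:
        return 1 + self.k_cn

    @property
    def fwhm(self) -> float:
        """Lorentzian full width at half maximum, Hz."""
        return self.r2 / np.pi

    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell

    def axis(self, nucleus: str) -> Axis:
        n = self.n_points * self.zero_fill_factor
        hz = np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell))
        return Axis(hz, nucleus, self.carrier, self.field_mhz)


def apparent_splitting(j: float, k: int) -> float:
    """Apparent splitting (Hz) of a coupling J under echo increment k·dw.

    One period of coupling evolution comes from t₁ itself and k more from
    the enhancement echo, so the observed splitting is ``(1 + k)·J``.
    """
    if j < 0:
        raise ValidationError(f"coupling magnitude must be ≥ 0, got {j}")
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ValidationError(f"k must be a non-negative integer, got {k!r}")
    return (1 + k) * j


def carbon_fid(
    template: SpinSystemTemplate,
    mixture: IsotopomerMixture,
    observed_site: int,
    acq: AcquisitionParams,
) -> np.ndarray:
    """Complex time-domain signal of one carbon site's ¹³C trace.

    Each isotopomer carrying ¹³C at ``observed_site`` contributes its
    fraction, offset-modulated at the site's shift and cosine-modulated by
    every coupling to an isotopically active neighbour; the enhancement
    multipliers stretch the coupling evolution only.
    """
    site = template.carbon(observed_site)
    if site.n_attached_protons == 0:
        raise ValidationError(
            f"site {observed_site} is HSQC-invisible (no attached protons)"
        )
    t = acq.times()
    omega = (site.carbon_shift - acq.carrier) * acq.field_mhz  # Hz offset
    _warn_if_aliased(template, observed_site, acq, omega)
    fid = np.zeros(acq.n_points, dtype=complex)
    for iso, frac in mixture:
        if frac == 0.0 or not iso.carbon_labels.get(observed_site, False):
            continue
        sig = frac * np.exp(2j * np.pi * omega * t)
        for other, j in template.carbon_couplings(observed_site):
            if iso.carbon_labels.get(other, False):
                sig = sig * np.cos(np.pi * abs(j) * acq.e_cc * t)
        for nsite, j in template.nitrogen_couplings(observed_site):
            if iso.nitrogen_labels.get(nsite, False):
                sig = sig * np.cos(np.pi * abs(j) * acq.e_cn * t)
        fid += sig
    fid *= np.exp(-acq.r2 * t)
    return fid


def _warn_if_aliased(
    template: SpinSystemTemplate,
    observed_site: int,
    acq: AcquisitionParams,
    omega: float,
) -> None:
    spread = sum(
        abs(j) * acq.e_cc / 2 for _, j in template.carbon_couplings(observed_site)
    ) + sum(abs(j) * acq.e_cn / 2 for _, j in template.nitrogen_couplings(observed_site))
    if abs(omega) + spread > acq.spectral_width / 2:
        warnings.warn(
            f"site {observed_site}: multiplet extent {abs(omega) + spread:.1f} Hz "
            f"exceeds half the spectral width ({acq.spectral_width / 2:.1f} Hz); "
            "lines will alias",
            stacklevel=3,
        )


def fid_to_spectrum(
    fid: np.ndarray, acq: AcquisitionParams, nucleus: str = "13C"
) -> Spectrum1D:
    """Zero-fill, Fourier transform and phase a time-domain signal.

    The first point is halved (standard DC-offset correction for a
    half-echo sampling grid), so the spectrum integral equals the t=0
    amplitude and is conserved under any splitting enhancement.
    """
    fid = np.asarray(fid, dtype=complex)
    if len(fid) != acq.n_points:
        raise ValidationError("FID length does not match acq.n_points")
    work = fid.copy()
    work[0] *= 0.5
    n = acq.n_points * acq.zero_fill_factor
    ft = np.fft.fftshift(np.fft.fft(work, n=n))
    # absorptive real part, optionally blended with the dispersive imaginary
    d = acq.dispersive_fraction
    intensity = (1.0 - d) * ft.real + d * ft.imag
    # scale by dwell/zero-fill so the trapezoidal integral over Hz ≈ s(0)
    intensity = intensity * acq.dwell
    return Spectrum1D(acq.axis(nucleus), intensity, {"nucleus": nucleus})


def simulate_carbon_trace(
    template: SpinSystemTemplate,
    mixture: IsotopomerMixture,
    observed_site: int,
    acq: AcquisitionParams,
) -> Spectrum1D:
    """Simulated ¹³C trace of an HSQC multiplet at one proton position.

    Returns the frequency-domain absorptive spectrum for the observed
    carbon site.  The total integral is proportional to the summed
    fractions of the contributing (¹³C-at-site) isotopomers, independent
    of the enhancement multipliers: enhancement moves intensity between
    lines, it never creates or destroys it.
    """
    fid = carbon_fid(template, mixture, observed_site, acq)
    spec = fid_to_spectrum(fid, acq, nucleus="13C")
    spec.meta.update(
        {
            "template": template.name,
            "observed_site": observed_site,
            "k_cc": acq.k_cc,
            "k_cn": acq.k_cn,
        }
    )
    return spec


def simulate_satellite_spectrum(
    template: SpinSystemTemplate,
    observed_site: int,
    fraction_13c: float,
    acq_1h: AcquisitionParams,
    decouple_13c: bool = False,
) -> Spectrum1D:
    """1D ¹H spectrum of one proton resonance with its ¹³C satellites.

    Protons on ¹²C give a central line of weight ``1 − fraction_13c``;
    protons on ¹³C split into two satellites of weight ``fraction_13c/2``
    displaced ±J_CH/2 (collapsing onto the centre when ``decouple_13c``).
    With ``fraction_13c = 0.0107`` (natural abundance) each satellite is
    ≈0.5% of the central peak height.
    """
    if not 0.0 <= fraction_13c <= 1.0:
        raise ValidationError("fraction_13c must be in [0, 1]")
    site = template.carbon(observed_site)
    t = acq_1h.times()
    omega = (site.proton_shift - acq_1h.carrier) * acq_1h.field_mhz
    base = np.exp(2j * np.pi * omega * t)
    fid = (1.0 - fraction_13c) * base
    if decouple_13c:
        fid = fid + fraction_13c * base
    else:
        fid = fid + fraction_13c * base * np.cos(np.pi * site.j_ch * t)
    fid *= np.exp(-acq_1h.r2 * t)
    spec = fid_to_spectrum(fid, acq_1h, nucleus="1H")
    spec.meta.update({"observed_site": observed_site, "fraction_13c": fraction_13c})
    return spec


def apply_species_filter(
    mixture: IsotopomerMixture,
    observed_site: int,
    template: SpinSystemTemplate,
    mode: str = "none",
) -> IsotopomerMixture:
    """Isotope-species selection as performed by a ¹⁵N spectral filter.

    ``mode="require_15N_neighbour"`` keeps only isotopomers in which some
    nitrogen coupled to the observed carbon (j_cn ≠ 0) is ¹⁵N.  Fractions
    are *not* renormalised: the filter removes signal from the spectrum,
    it does not rescale the survivors.
    """
    if mode not in ("none", "require_15N_neighbour"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    template.carbon(observed_site)  # raises KeyError if absent
    if mode == "none":
        return mixture
    coupled = [n for n, _ in template.nitrogen_couplings(observed_site)]
    kept = tuple(
        (iso, f)
        for iso, f in mixture
        if any(iso.nitrogen_labels.get(n, False) for n in coupled)
    )
    return IsotopomerMixture(kept, partial=True)


# ---------------------------------------------------------------------------
# Long-range ¹H,¹⁵N-HSQC
# ---------------------------------------------------------------------------


def simulate_nh2d_components(
    components: list[tuple[SpinSystemTemplate, Isotopomer, float]],
    acq_f1: AcquisitionParams,
    acq_f2: AcquisitionParams,
    proton_site: int | None = None,
    nitrogen_site: str | None = None,
) -> Spectrum2D:
    """Long-range ¹H,¹⁵N 2D multiplet from explicit species components.

    Magnetisation starts on Hα and reaches the nitrogen through the
    two-bond H–N coupling, so only ¹⁵N species appear.  In F2 the proton
    line is split by ¹J_CH when its carbon is ¹³C; in F1 the nitrogen line
    is split by ``E_cn·J_CN`` for every ¹³C-labelled coupled carbon.  Each
    active splitting halves the line weight, so a doubly split species
    spreads its fraction over four 2D Lorentzian components.

    Accepting (template, isotopomer, fraction) triples allows species with
    different effective coupling tables — e.g. a sub-population whose C–N
    coupling is unresolvably small — to coexist in one spectrum.
    """
    if not components:
        raise ValidationError("no species components given")
    t1 = acq_f1.times()
    t2 = acq_f2.times()
    f1_spec = np.zeros(acq_f1.n_points * acq_f1.zero_fill_factor)
    out = None
    total_weight = 0.0
    for template, iso, frac in components:
        n_id = nitrogen_site
        if n_id is None:
            if not template.nitrogens:
                raise ValidationError(f"{template.name!r} has no nitrogen sites")
            n_id = template.nitrogens[0].site_id
        nsite = template.nitrogen(n_id)
        if not iso.nitrogen_labels.get(n_id, False):
            continue  # ¹⁴N species are invisible through the ¹⁵N filter
        p_id = proton_site
        if p_id is None:
            p_id = _default_proton_site(template, n_id)
        csite = template.carbon(p_id)
        # F1 (15N) interferogram
        om1 = (nsite.nitrogen_shift - acq_f1.carrier) * acq_f1.field_mhz
        sig1 = np.exp(2j * np.pi * om1 * t1)
        for c_id, j in sorted(template.j_cn.items()):
            c, n = c_id
            if n == n_id and j != 0.0 and iso.carbon_labels.get(c, False):
                sig1 = sig1 * np.cos(np.pi * abs(j) * acq_f1.e_cn * t1)
        sig1 = sig1 * np.exp(-acq_f1.r2 * t1)
        trace1 = fid_to_spectrum(sig1, acq_f1, nucleus="15N").intensity
        # F2 (1H) line, split by 1J_CH iff the proton-bearing carbon is 13C
        om2 = (csite.proton_shift - acq_f2.carrier) * acq_f2.field_mhz
        sig2 = np.exp(2j * np.pi * om2 * t2)
        if iso.carbon_labels.get(p_id, False):
            sig2 = sig2 * np.cos(np.pi * csite.j_ch * t2)
        sig2 = sig2 * np.exp(-acq_f2.r2 * t2)
        trace2 = fid_to_spectrum(sig2, acq_f2, nucleus="1H").intensity
        plane = frac * np.outer(trace1, trace2)
        out = plane if out is None else out + plane
        total_weight += frac
    if out is None or total_weight == 0.0:
        warnings.warn("no ¹⁵N-containing species in mixture; spectrum is empty")
        n1 = acq_f1.n_points * acq_f1.zero_fill_factor
        n2 = acq_f2.n_points * acq_f2.zero_fill_factor
        out = np.zeros((n1, n2))
    return Spectrum2D(
        acq_f1.axis("15N"),
        acq_f2.axis("1H"),
        out,
        {"experiment": "long-range 1H,15N-HSQC"},
    )


def _default_proton_site(template: SpinSystemTemplate, nitrogen_id: str) -> int:
    """The carbon whose proton sources the long-range transfer: the
    protonated carbon most strongly coupled to the nitrogen (Hα)."""
    best = None
    best_j = -1.0
    for (c, n), j in template.j_cn.items():
        if n != nitrogen_id:
            continue
        site = template.carbon(c)
        if site.n_attached_protons > 0 and abs(j) > best_j:
            best, best_j = c, abs(j)
    if best is None:
        raise ValidationError(
            f"no protonated carbon coupled to nitrogen {nitrogen_id!r}"
        )
    return best


def simulate_long_range_nh_2d(
    template: SpinSystemTemplate,
    mixture: IsotopomerMixture,
    acq_f1: AcquisitionParams,
    acq_f2: AcquisitionParams,
    proton_site: int | None = None,
    nitrogen_site: str | None = None,
) -> Spectrum2D:
    """Long-range ¹H,¹⁵N-HSQC multiplet of a labelled mixture.

    Convenience wrapper over :func:`simulate_nh2d_components` for mixtures
    sharing one coupling table.
    """
    components = [(template, iso, f) for iso, f in mixture]
    return simulate_nh2d_components(
        components, acq_f1, acq_f2, proton_site=proton_site, nitrogen_site=nitrogen_site
    )


# ---------------------------------------------------------------------------
# Peak counting / picking
# ---------------------------------------------------------------------------


def count_components(
    spectrum2d: Spectrum2D,
    rel_threshold: float = 0.05,
    min_separation_lines: int = 3,
) -> int:
    """Count resolved 2D multiplet components.

    A component is a local maximum whose intensity is at least
    ``rel_threshold`` of the global maximum; maxima closer than
    ``min_separation_lines`` grid points in *both* axes are merged into
    the stronger one.  Deterministic; an all-zero spectrum counts 0.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValidationError("rel_threshold must be in (0, 1)")
    z = spectrum2d.intensity
    peak = z.max()
    if peak <= 0.0:
        return 0
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (z == ndimage.maximum_filter(z, footprint=footprint)) & (
        z >= rel_threshold * peak
    )
    coords = np.argwhere(is_max)
    if len(coords) == 0:
        return 0
    order = np.argsort(-z[coords[:, 0], coords[:, 1]], kind="stable")
    accepted: list[np.ndarray] = []
    for i in order:
        c = coords[i]
        merged = any(
            abs(c[0] - a[0]) < min_separation_lines
            and abs(c[1] - a[1]) < min_separation_lines
            for a in accepted
        )
        if not merged:
            accepted.append(c)
    return len(accepted)


def pick_peaks_1d(
    spectrum: Spectrum1D, rel_threshold: float = 0.1
) -> list[tuple[float, float]]:
    """Local maxima above ``rel_threshold`` of the global maximum.

    Returns (frequency offset in Hz, height) sorted by frequency.
    """
    y = spectrum.intensity
    top = y.max()
    if top <= 0:
        return []
    idx = np.where((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] >= rel_threshold * top))[0] + 1
    return [(float(spectrum.hz[i]), float(y[i])) for i in idx]


def measure_splitting(spectrum: Spectrum1D, rel_threshold: float = 0.3) -> float:
    """Frequency separation (Hz) of the two outermost resolved lines."""
    peaks = pick_peaks_1d(spectrum, rel_threshold)
    if len(peaks) < 2:
        raise ValidationError("fewer than two resolved lines; no splitting to measure")
    return peaks[-1][0] - peaks[0][0]


def with_enhancement(acq: AcquisitionParams, k_cc: int | None = None,
                     k_cn: int | None = None) -> AcquisitionParams:
    """Copy acquisition parameters with new enhancement increments."""
    kwargs = {}
    if k_cc is not None:
        kwargs["k_cc"] = k_cc
    if k_cn is not None:
        kwargs["k_cn"] = k_cn
    return replace(acq, **kwargs)
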