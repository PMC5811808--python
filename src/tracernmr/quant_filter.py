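"""Quantitative ¹²C/¹³C spectral-filter analysis of paired 1D ¹H spectra.

Absolute per-peak ¹³C incorporation from a single sample: one spectrum
records all protons, a second records only ¹³C-bound protons, and the two
share an intensity scale.  The filtered spectrum is attenuated by
sin²(2πδJ_CH), where δ is the filter's spin-echo delay; with the usual
tuning δ = 1/(4·J_CH) the factor is exactly 1 at the nominal coupling and
falls off slowly for mistuned peaks — at δ tuned to 145 Hz the worst case
over J_CH ∈ [120, 165] Hz is a 7.2 % downscaling, which the correction in
:func:`incorporation_percent` removes when the peak's true J_CH is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum1D
from .spin_systems import ValidationError

__all__ = [
    "FilterPair",
    "PeakRegion",
    "IncorporationResult",
    "attenuation_factor",
    "max_downscaling",
    "incorporation_percent",
    "read_regions_csv",
    "write_results_csv",
]

#: Background ¹³C fraction present without any tracer, as percent.
NATURAL_ABUNDANCE_PERCENT = 1.07


def attenuation_factor(j_ch: float, delta: float) -> float:
    """Filter transmission sin²(2π·δ·J_CH) for a peak with coupling J_CH.

    Equals 1 exactly when δ = 1/(4·J_CH) (the argument is then π/2) and
    decreases monotonically as J_CH moves away from the tuned value within
    the half-period around it.  Warns below 0.5: the peak is then far off
    the filter's tuning and the correction becomes unreliable.
    """
    if j_ch <= 0:
        raise ValidationError("j_ch must be > 0 Hz")
    if delta <= 0:
        raise ValidationError("delta must be > 0 s")
    factor = float(np.sin(2.0 * np.pi * delta * j_ch) ** 2)
    if factor <= 0.5:
        warnings.warn(
            f"attenuation factor {factor:.3f} for J_CH = {j_ch:g} Hz: "
            "J far off resonance of filter tuning",
            stacklevel=2,
        )
    return factor


def max_downscaling(j_min: float, j_max: float, delta: float) -> float:
    """Worst-case percent signal loss over a J_CH range, for a given δ.

    The transmission is monotone on each side of the tuned coupling
    1/(4δ), so the maximum loss occurs at whichever endpoint of
    ``[j_min, j_max]`` lies further (in transmission) from the tuning.
    """
    if not 0 < j_min <= j_max:
        raise ValidationError("need 0 < j_min ≤ j_max")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates = [j_min, j_max]
        j_tuned = 1.0 / (4.0 * delta)
        if j_min <= j_tuned <= j_max:
            candidates.append(j_tuned)
        worst = max(1.0 - attenuation_factor(j, delta) for j in candidates)
    return 100.0 * worst


@dataclass
class FilterPair:
    """The two spectra of one filtered-quantification measurement.

    ``spectrum_all`` records every proton; ``spectrum_filtered`` only the
    ¹³C-bound protons, attenuated by the J-dependent filter factor.  The
    acquisition guarantees identical intensity scaling of the two, which
    is what makes single-sample absolute quantification possible.
    """

    spectrum_all: Spectrum1D
    spectrum_filtered: Spectrum1D
    delta: float = 1.0 / (4.0 * 145.0)
    j_ch_nominal: float = 145.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError("delta must be > 0")
        if not self.spectrum_all.same_axis(self.spectrum_filtered):
            # interpolate the filtered spectrum onto the reference grid
            interp = np.interp(
                self.spectrum_all.hz,
                self.spectrum_filtered.hz,
                self.spectrum_filtered.intensity,
                left=0.0,
                right=0.0,
            )
            self.spectrum_filtered = Spectrum1D(
                self.spectrum_all.axis, interp, dict(self.spectrum_filtered.meta)
            )


@dataclass
class PeakRegion:
    """An integration window with the peak's actual one-bond coupling."""

    label: str
    ppm_low: float
    ppm_high: float
    j_ch_actual: float = 145.0

    def __post_init__(self) -> None:
        if not self.ppm_low < self.ppm_high:
            raise ValidationError(f"{self.label}: ppm_low must be < ppm_high")
        if not 100.0 <= self.j_ch_actual <= 250.0:
            raise ValidationError(
                f"{self.label}: j_ch_actual {self.j_ch_actual} Hz outside "
                "the plausible one-bond range [100, 250]"
            )


@dataclass
class IncorporationResult:
    label: str
    percent: float
    sigma: float
    factor_used: float
    integral_all: float
    integral_filtered: float
    warnings: list[str] = field(default_factory=list)


def _region_integral(spec: Spectrum1D, region: PeakRegion,
                     local_baseline: bool) -> tuple[float, int]:
    ppm = spec.ppm
    mask = (ppm >= region.ppm_low) & (ppm <= region.ppm_high)
    n = int(mask.sum())
    if n < 2:
        raise ValidationError(
            f"region {region.label!r} covers {n} point(s) of the spectrum axis"
        )
    x = spec.hz[mask]
    y = spec.intensity[mask].copy()
    if local_baseline:
        # straight line through the window's edge points
        y = y - np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    return float(np.trapezoid(y, x)), n


def _noise_sigma(spec: Spectrum1D, noise_region: tuple[float, float]) -> float:
    ppm = spec.ppm
    mask = (ppm >= noise_region[0]) & (ppm <= noise_region[1])
    if mask.sum() < 8:
        raise ValidationError("noise region covers too few points")
    seg = spec.intensity[mask]
    return float(np.sqrt(np.mean((seg - seg.mean()) ** 2)))


def incorporation_percent(
    pair: FilterPair,
    region: PeakRegion,
    correct_attenuation: bool = True,
    noise_region: tuple[float, float] | None = None,
    local_baseline: bool = False,
    subtract_natural_abundance: bool = False,
) -> IncorporationResult:
    """Percent ¹³C incorporation of one peak from a filtered pair.

    Integrates both spectra over the region (trapezoidal sum on the common
    grid), divides the filtered integral by the sin²(2πδJ) transmission
    when correcting, and reports ``100·(I_filt/factor)/I_all``.  The
    1-σ uncertainty propagates the baseline noise of each integral
    (RMS of a signal-free region × grid step × √points).  By default the
    result includes the ~1.07 % natural-abundance background;
    ``subtract_natural_abundance`` removes it.
    """
    notes: list[str] = []
    factor = 1.0
    if correct_attenuation:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            factor = attenuation_factor(region.j_ch_actual, pair.delta)
        notes.extend(str(w.message) for w in caught)
    i_all, n_pts = _region_integral(pair.spectrum_all, region, local_baseline)
    i_filt, _ = _region_integral(pair.spectrum_filtered, region, local_baseline)
    if i_all <= 0:
        raise ValidationError(f"empty reference region {region.label!r}")
    percent = 100.0 * (i_filt / factor) / i_all
    sigma = float("nan")
    if noise_region is not None:
        step = pair.spectrum_all.axis.step_hz
        s_all = _noise_sigma(pair.spectrum_all, noise_region) * step * np.sqrt(n_pts)
        s_filt = (
            _noise_sigma(pair.spectrum_filtered, noise_region) * step * np.sqrt(n_pts)
        )
        # ratio propagation; the factor is exact
        sigma = percent * np.sqrt(
            (s_filt / max(abs(i_filt), 1e-300)) ** 2 + (s_all / i_all) ** 2
        )
        if percent > 100.0 + 3.0 * sigma:
            msg = "scaling mismatch between paired spectra (result > 100% + 3σ)"
            warnings.warn(msg)
            notes.append(msg)
    elif percent > 100.5:  # allow sub-percent discretisation excess
        msg = "scaling mismatch between paired spectra (result > 100%)"
        warnings.warn(msg)
        notes.append(msg)
    if subtract_natural_abundance:
        percent -= NATURAL_ABUNDANCE_PERCENT
    return IncorporationResult(
        label=region.label,
        percent=percent,
        sigma=sigma,
        factor_used=factor,
        integral_all=i_all,
        integral_filtered=i_filt,
        warnings=notes,
    )


# -- region lists and result tables ----------------------------------------


def read_regions_csv(path: str | Path) -> list[PeakRegion]:
    """Regions from a CSV/TSV with columns label, ppm_low, ppm_high, j_ch."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"label", "ppm_low", "ppm_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"region table missing columns {sorted(missing)}")
    regions = []
    for _, row in df.iterrows():
        regions.append(
            PeakRegion(
                label=str(row["label"]),
                ppm_low=float(row["ppm_low"]),
                ppm_high=float(row["ppm_high"]),
                j_ch_actual=float(row.get("j_ch", 145.0)),
            )
        )
    return regions


def write_results_csv(results: list[IncorporationResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": r.label,
                "percent": r.percent,
                "sigma": r.sigma,
                "factor_used": r.factor_used,
            }
            for r in results
        ]
    ).to_csv(path, index=False)
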