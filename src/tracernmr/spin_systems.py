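"""Metabolite spin systems, isotopomers and labelled mixtures.

A metabolite fragment is described by its carbon (and optionally nitrogen)
sites, their chemical shifts, and a scalar-coupling table.  An isotopomer is
one positional isotope-labelling pattern over those sites (¹³C vs ¹²C,
¹⁵N vs ¹⁴N); a mixture assigns fractions to isotopomers.  These types are
the inputs to the multiplet simulator and the fitting routines.

Naming follows the bracket convention used throughout tracer metabolomics:
``[3-13C]`` for alanine labelled at C3, ``[2,3-13C]``, ``[U-13C]`` for
uniform carbon labelling, ``[U-13C,15N]`` when all nitrogens are labelled
too, and ``[unlabelled]`` for the all-¹²C/¹⁴N pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CarbonSite",
    "NitrogenSite",
    "SpinSystemTemplate",
    "Isotopomer",
    "IsotopomerMixture",
    "canonical_isotopomer_name",
    "enumerate_isotopomers",
    "validate_template",
    "template_to_dict",
    "template_from_dict",
    "mixture_to_dict",
    "mixture_from_dict",
]

#: Typical one-bond ¹H–¹³C coupling for sp³ CH groups, Hz.
DEFAULT_J_CH = 145.0

MAX_ENUMERATED_SITES = 20
FRACTION_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a spin-system description violates its invariants."""


@dataclass(frozen=True)
class CarbonSite:
    """One carbon position of a metabolite fragment.

    Parameters
    ----------
    site_id
        IUPAC carbon position number (C1 = carboxyl/anomeric carbon), so
        alanine's methyl is site 3 and glucose's hydroxymethyl is site 6.
    carbon_shift
        ¹³C chemical shift in ppm.
    proton_shift
        Chemical shift (ppm) of the attached proton(s).  Ignored when
        ``n_attached_protons == 0``.
    n_attached_protons
        0–3.  Proton-less carbons (carboxyls, quaternaries) give no direct
        HSQC cross peak; they enter the spectrum only through couplings to
        protonated neighbours.
    j_ch
        One-bond ¹H–¹³C coupling in Hz (used for satellites and for the
        F2 splitting in long-range ¹H,¹⁵N spectra).
    """

    site_id: int
    carbon_shift: float
    proton_shift: float = 0.0
    n_attached_protons: int = 1
    j_ch: float = DEFAULT_J_CH

    def __post_init__(self) -> None:
        if self.site_id <= 0:
            raise ValidationError(f"carbon site_id must be positive, got {self.site_id}")
        if not 0 <= self.n_attached_protons <= 3:
            raise ValidationError(
                f"n_attached_protons must be 0..3, got {self.n_attached_protons}"
            )
        if self.j_ch <= 0:
            raise ValidationError(f"j_ch must be > 0 Hz, got {self.j_ch}")


@dataclass(frozen=True)
class NitrogenSite:
    """A nitrogen position, detected through its two-bond coupling to Hα."""

    site_id: str
    nitrogen_shift: float
    j_hn_long_range: float = 0.0


@dataclass(frozen=True)
class SpinSystemTemplate:
    """A metabolite fragment: sites plus the scalar-coupling tables.

    ``j_cc`` maps unordered carbon-site pairs to Hz (stored under both
    orderings for convenience); ``j_cn`` maps (carbon site, nitrogen site)
    pairs.  Couplings are stored signed but the simulator uses ``abs(J)``:
    only splitting magnitudes are observable in these experiments.
    """

    name: str
    carbons: tuple[CarbonSite, ...]
    nitrogens: tuple[NitrogenSite, ...] = ()
    j_cc: Mapping[tuple[int, int], float] = field(default_factory=dict)
    j_cn: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "carbons", tuple(self.carbons))
        object.__setattr__(self, "nitrogens", tuple(self.nitrogens))
        # symmetrise j_cc so lookups work under either ordering
        sym: dict[tuple[int, int], float] = {}
        for (a, b), j in dict(self.j_cc).items():
            if (b, a) in self.j_cc and self.j_cc[(b, a)] != j:
                # keep as given; validate_template will report the asymmetry
                sym[(a, b)] = j
            else:
                sym[(a, b)] = j
                sym.setdefault((b, a), j)
        object.__setattr__(self, "j_cc", sym)
        object.__setattr__(self, "j_cn", dict(self.j_cn))
        # construction is permissive; call validate_template() to get a
        # report of invariant violations without raising

    # -- lookups -----------------------------------------------------------
    @property
    def carbon_ids(self) -> tuple[int, ...]:
        return tuple(c.site_id for c in self.carbons)

    @property
    def nitrogen_ids(self) -> tuple[str, ...]:
        return tuple(n.site_id for n in self.nitrogens)

    def carbon(self, site_id: int) -> CarbonSite:
        for c in self.carbons:
            if c.site_id == site_id:
                return c
        raise KeyError(f"{self.name!r} has no carbon site {site_id}")

    def nitrogen(self, site_id: str) -> NitrogenSite:
        for n in self.nitrogens:
            if n.site_id == site_id:
                return n
        raise KeyError(f"{self.name!r} has no nitrogen site {site_id!r}")

    def carbon_couplings(self, site_id: int) -> list[tuple[int, float]]:
        """(other carbon site, J/Hz) pairs coupled to ``site_id``."""
        out = []
        for (a, b), j in self.j_cc.items():
            if a == site_id and j != 0.0:
                out.append((b, j))
        return sorted(set(out))

    def nitrogen_couplings(self, site_id: int) -> list[tuple[str, float]]:
        """(nitrogen site, J/Hz) pairs coupled to carbon ``site_id``."""
        out = [
            (n, j) for (c, n), j in self.j_cn.items() if c == site_id and j != 0.0
        ]
        return sorted(set(out))


def validate_template(template: SpinSystemTemplate) -> list[str]:
    """Check a template's invariants; return human-readable violations.

    Never raises: an empty list means the template is well formed.
    """
    import math

    violations: list[str] = []
    cids = [c.site_id for c in template.carbons]
    nids = [n.site_id for n in template.nitrogens]
    if len(set(cids)) != len(cids):
        violations.append(f"duplicate carbon site_ids in {template.name!r}")
    if len(set(nids)) != len(nids):
        violations.append(f"duplicate nitrogen site_ids in {template.name!r}")
    for (a, b), j in template.j_cc.items():
        if a == b:
            violations.append(f"j_cc self-coupling on site {a}")
        if a not in cids or b not in cids:
            violations.append(f"j_cc({a},{b}) references a missing carbon site")
        elif template.j_cc.get((b, a)) != j:
            violations.append(f"j_cc asymmetric for pair ({a},{b})")
        if not math.isfinite(j):
            violations.append(f"j_cc({a},{b}) is not finite")
    for (c, n), j in template.j_cn.items():
        if c not in cids:
            violations.append(f"j_cn({c},{n!r}) references a missing carbon site")
        if n not in nids:
            violations.append(f"j_cn({c},{n!r}) references a missing nitrogen site")
        if not math.isfinite(j):
            violations.append(f"j_cn({c},{n!r}) is not finite")
    return violations


@dataclass(frozen=True)
class Isotopomer:
    """One positional labelling pattern over a template's sites.

    ``carbon_labels[site_id]`` is True for ¹³C, False for ¹²C; likewise
    ``nitrogen_labels`` for ¹⁵N vs ¹⁴N.  The canonical name is a pure
    function of the label vectors (see :func:`canonical_isotopomer_name`).
    """

    carbon_labels: Mapping[int, bool]
    nitrogen_labels: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "carbon_labels", dict(self.carbon_labels))
        object.__setattr__(self, "nitrogen_labels", dict(self.nitrogen_labels))

    def name(self, template: SpinSystemTemplate) -> str:
        return canonical_isotopomer_name(
            self.carbon_labels, self.nitrogen_labels, template
        )

    def _key(self) -> tuple:
        return (
            tuple(sorted(self.carbon_labels.items())),
            tuple(sorted(self.nitrogen_labels.items())),
        )

    def __hash__(self) -> int:
        return hash(self._key())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Isotopomer):
            return NotImplemented
        return self._key() == other._key()


def canonical_isotopomer_name(
    carbon_labels: Mapping[int, bool],
    nitrogen_labels: Mapping[str, bool],
    template: SpinSystemTemplate,
) -> str:
    """Bracket-notation name for a labelling pattern.

    ``[3-13C]``, ``[2,3-13C]``, ``[U-13C]`` (all carbons), ``[15N]``,
    ``[U-13C,15N]`` and ``[unlabelled]``.  Uniform labelling over an
    element's sites collapses to the ``U-`` form; nitrogen is written
    ``15N`` without positions when the template has a single nitrogen.
    Deterministic and injective over distinct label vectors.
    """
    if set(carbon_labels) != set(template.carbon_ids):
        raise ValidationError(
            f"carbon label vector {sorted(carbon_labels)} does not match "
            f"template sites {sorted(template.carbon_ids)}"
        )
    if set(nitrogen_labels) != set(template.nitrogen_ids):
        raise ValidationError(
            f"nitrogen label vector {sorted(nitrogen_labels)} does not match "
            f"template sites {sorted(template.nitrogen_ids)}"
        )
    c_on = sorted(s for s, lab in carbon_labels.items() if lab)
    n_on = sorted(s for s, lab in nitrogen_labels.items() if lab)
    parts: list[str] = []
    if c_on:
        if len(c_on) == len(template.carbon_ids):
            parts.append("U-13C")
        else:
            parts.append(",".join(str(s) for s in c_on) + "-13C")
    if n_on:
        if len(n_on) == len(template.nitrogen_ids):
            parts.append("15N" if len(n_on) == 1 else "U-15N")
        else:
            parts.append(",".join(str(s) for s in n_on) + "-15N")
    if not parts:
        return "[unlabelled]"
    return "[" + ",".join(parts) + "]"


def enumerate_isotopomers(
    template: SpinSystemTemplate,
    element_scope: Iterable[str] = ("carbon",),
) -> list[Isotopomer]:
    """All 2^n labelling patterns over the scoped sites, in a fixed order.

    Sites outside the scope are left unlabelled.  Patterns are ordered by
    the binary counting order of the (sorted) scoped sites, so the first
    entry is fully unlabelled and the last fully labelled.  Refuses more
    than 20 scoped sites.
    """
    scope = set(element_scope)
    unknown = scope - {"carbon", "nitrogen"}
    if unknown:
        raise ValidationError(f"unknown element scope {sorted(unknown)}")
    c_sites = sorted(template.carbon_ids) if "carbon" in scope else []
    n_sites = sorted(template.nitrogen_ids) if "nitrogen" in scope else []
    n_total = len(c_sites) + len(n_sites)
    if n_total > MAX_ENUMERATED_SITES:
        raise ValidationError(
            f"refusing to enumerate 2^{n_total} isotopomers (> 2^{MAX_ENUMERATED_SITES})"
        )
    out: list[Isotopomer] = []
    for pattern in range(2**n_total):
        bits = [(pattern >> i) & 1 for i in range(n_total)]
        c_labels = {s: False for s in template.carbon_ids}
        n_labels = {s: False for s in template.nitrogen_ids}
        for i, s in enumerate(c_sites):
            c_labels[s] = bool(bits[i])
        for i, s in enumerate(n_sites):
            n_labels[s] = bool(bits[len(c_sites) + i])
        out.append(Isotopomer(c_labels, n_labels))
    return out


@dataclass(frozen=True)
class IsotopomerMixture:
    """Isotopomers with fractions; fractions are ≥ 0 and sum to 1.

    A ``partial`` mixture (fractions summing to less than 1) represents the
    surviving signal after an isotope-species filter, which removes entries
    without renormalising the rest.
    """

    entries: tuple[tuple[Isotopomer, float], ...]
    partial: bool = False

    def __post_init__(self) -> None:
        entries = tuple((iso, float(f)) for iso, f in self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            return  # empty mixtures arise from species filtering
        for iso, f in entries:
            if f < 0:
                raise ValidationError(f"negative fraction {f}")
        isos = [iso for iso, _ in entries]
        if len(set(isos)) != len(isos):
            raise ValidationError("duplicate isotopomers in mixture")
        total = sum(f for _, f in entries)
        if self.partial:
            if total > 1.0 + FRACTION_SUM_TOL:
                raise ValidationError(f"fractions sum to {total!r}, expected ≤ 1")
        elif abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValidationError(f"fractions sum to {total!r}, expected 1")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_fractions(
        cls, pairs: Sequence[tuple[Isotopomer, float]]
    ) -> "IsotopomerMixture":
        return cls(tuple(pairs))

    def fractions_by_name(self, template: SpinSystemTemplate) -> dict[str, float]:
        return {iso.name(template): f for iso, f in self.entries}


# ---------------------------------------------------------------------------
# JSON serialisation
#
# Schema: {"name": str,
#          "carbons": [{"site_id", "carbon_shift", "proton_shift",
#                       "n_attached_protons", "j_ch"}, ...],
#          "nitrogens": [{"site_id", "nitrogen_shift", "j_hn_long_range"}, ...],
#          "j_cc": [[site_a, site_b, hz], ...],   # one triple per pair
#          "j_cn": [[carbon_site, nitrogen_site, hz], ...]}
# Mixtures: {"mixture": [{"carbon_labels": {"2": true, ...},
#                         "nitrogen_labels": {...}, "fraction": 0.5}, ...]}
# ---------------------------------------------------------------------------


def template_to_dict(template: SpinSystemTemplate) -> dict:
    seen: set[tuple[int, int]] = set()
    j_cc = []
    for (a, b), j in sorted(template.j_cc.items()):
        if (b, a) in seen or (a, b) in seen:
            continue
        seen.add((a, b))
        j_cc.append([a, b, j])
    return {
        "name": template.name,
        "carbons": [
            {
                "site_id": c.site_id,
                "carbon_shift": c.carbon_shift,
                "proton_shift": c.proton_shift,
                "n_attached_protons": c.n_attached_protons,
                "j_ch": c.j_ch,
            }
            for c in template.carbons
        ],
        "nitrogens": [
            {
                "site_id": n.site_id,
                "nitrogen_shift": n.nitrogen_shift,
                "j_hn_long_range": n.j_hn_long_range,
            }
            for n in template.nitrogens
        ],
        "j_cc": j_cc,
        "j_cn": [[c, n, j] for (c, n), j in sorted(template.j_cn.items())],
    }


def template_from_dict(data: Mapping) -> SpinSystemTemplate:
    return SpinSystemTemplate(
        name=data["name"],
        carbons=tuple(CarbonSite(**c) for c in data["carbons"]),
        nitrogens=tuple(NitrogenSite(**n) for n in data.get("nitrogens", ())),
        j_cc={(a, b): j for a, b, j in data.get("j_cc", ())},
        j_cn={(c, n): j for c, n, j in data.get("j_cn", ())},
    )


def mixture_to_dict(
    mixture: IsotopomerMixture, template: SpinSystemTemplate | None = None
) -> dict:
    entries = []
    for iso, f in mixture:
        d = {
            "carbon_labels": {str(k): v for k, v in sorted(iso.carbon_labels.items())},
            "nitrogen_labels": dict(sorted(iso.nitrogen_labels.items())),
            "fraction": f,
        }
        if template is not None:
            d["name"] = iso.name(template)
        entries.append(d)
    return {"mixture": entries}


def mixture_from_dict(data: Mapping) -> IsotopomerMixture:
    entries = []
    for e in data["mixture"]:
        iso = Isotopomer(
            {int(k): bool(v) for k, v in e["carbon_labels"].items()},
            {str(k): bool(v) for k, v in e.get("nitrogen_labels", {}).items()},
        )
        entries.append((iso, float(e["fraction"])))
    return IsotopomerMixture(tuple(entries))


def load_template(path: str | Path) -> SpinSystemTemplate:
    with open(path) as fh:
        return template_from_dict(json.load(fh))


def save_template(template: SpinSystemTemplate, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(template_to_dict(template), fh, indent=2)


def load_mixture(path: str | Path) -> IsotopomerMixture:
    with open(path) as fh:
        return mixture_from_dict(json.load(fh))


def save_mixture(
    mixture: IsotopomerMixture,
    path: str | Path,
    template: SpinSystemTemplate | None = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(mixture_to_dict(mixture, template), fh, indent=2)
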