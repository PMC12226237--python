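"""Admixture model-space enumeration, parsimony filtering, and
representative-model selection.

Three model schemes are used for each target individual:

* *broad* — all 255 non-empty subsets of the eight proxy sources as
  lefts, against the core 14 right populations;
* *western* — the Levantine proxy is moved into the right set and the
  127 non-empty subsets of the seven remaining proxies are lefts;
* *eastern* — the three eastern proxies (Levantine, Iranian-Neolithic
  related, North African) form 7 left subsets while the five western
  proxies join the rights.

Among valid models (all weights non-negative, p >= 0.05) a model is
dropped as non-parsimonious when removing one source yields a valid
nested model that does not fit significantly worse by likelihood-ratio
test.  The representative model maximizes the main ancestry component
(Sicilian-Aegean for western models, Levantine for eastern ones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

from .fstats import AdmixtureModelFit, lrt_nested

CORE_RIGHTS: tuple[str, ...] = (
    "El_Miron",      # anchor, always first
    "Ust_Ishim",
    "Kostenki",
    "GoyetQ116",
    "Vestonice",
    "MA1",
    "Villabruna",
    "CHG",
    "EHG",
    "WHG",
    "Mota",
    "Natufian",
    "Levant_N",
    "Tunisia_N",
)

PROXY_SOURCES: tuple[str, ...] = (
    "Greece_BA",
    "Sicily_EMBA",
    "Sardinia_LBA",
    "Iberia_EBA",
    "Steppe_MLBA",
    "Iran_N",
    "Levant_MLBA",
    "NorthAfrica_IA",
)

EASTERN_PROXIES: tuple[str, ...] = ("Levant_MLBA", "Iran_N", "NorthAfrica_IA")

# grouped ancestry components used for reporting representative models
ANCESTRY_GROUPS: dict[str, tuple[str, ...]] = {
    "SicilianAegean": ("Greece_BA", "Sicily_EMBA"),
    "WesternMediterranean": ("Sardinia_LBA", "Iberia_EBA"),
    "NorthAfrica": ("NorthAfrica_IA",),
    "Levant": ("Levant_MLBA",),
    "IranN": ("Iran_N",),
    "SteppeMLBA": ("Steppe_MLBA",),
}


@dataclass(frozen=True)
class ModelScheme:
    """One family of admixture models: which proxies may be lefts and
    which are promoted into the right set."""

    name: str
    proxy_pool: tuple[str, ...]
    rights_extension: tuple[str, ...] = ()
    core_rights: tuple[str, ...] = CORE_RIGHTS

    def __post_init__(self) -> None:
        overlap = set(self.proxy_pool) & set(self.rights_extension)
        if overlap:
            raise ValueError(f"proxies cannot be both lefts and rights: {sorted(overlap)}")

    @property
    def right_set(self) -> tuple[str, ...]:
        return self.core_rights + self.rights_extension


def default_schemes(
    proxies: tuple[str, ...] = PROXY_SOURCES,
    eastern: tuple[str, ...] = EASTERN_PROXIES,
    core_rights: tuple[str, ...] = CORE_RIGHTS,
) -> dict[str, ModelScheme]:
    western_pool = tuple(p for p in proxies if p != "Levant_MLBA")
    western_ext = ("Levant_MLBA",) if "Levant_MLBA" in proxies else ()
    return {
        "broad": ModelScheme("broad", proxies, (), core_rights),
        "western": ModelScheme("western", western_pool, western_ext, core_rights),
        "eastern": ModelScheme(
            "eastern", eastern, tuple(p for p in proxies if p not in eastern), core_rights
        ),
    }


def enumerate_models(scheme: ModelScheme) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All non-empty left subsets of the scheme's proxy pool, each with
    the scheme's right set (anchor first): 2^k - 1 models for a k-proxy
    pool."""
    if not scheme.proxy_pool:
        raise ValueError(f"scheme {scheme.name!r} has an empty proxy pool")
    rights = scheme.right_set
    models = []
    for k in range(1, len(scheme.proxy_pool) + 1):
        for lefts in combinations(scheme.proxy_pool, k):
            models.append((lefts, rights))
    return models


def parsimony_filter(fits: list[AdmixtureModelFit], alpha: float = 0.05) -> list[AdmixtureModelFit]:
    """Valid fits that are not refuted by a valid one-source-smaller
    nested model.

    A valid model M is discarded when some valid M' with
    left(M') u {p} = left(M) has likelihood-ratio p-value >= ``alpha``
    (i.e. the extra source p does not significantly improve the fit).
    Invalid fits are never returned.
    """
    valid = [f for f in fits if f.valid]
    by_lefts = {frozenset(f.left_set): f for f in valid}
    kept = []
    for fit in valid:
        lefts = frozenset(fit.left_set)
        discard = False
        for p in lefts:
            smaller = by_lefts.get(lefts - {p})
            if smaller is not None and lrt_nested(smaller, fit) >= alpha:
                discard = True
                break
        if not discard:
            kept.append(fit)
    return kept


def grouped_weights(fit: AdmixtureModelFit) -> dict[str, float]:
    """Mixture weights aggregated into the reporting ancestry groups;
    sources outside every group keep their own name."""
    grouped: dict[str, float] = {}
    assigned = {src: grp for grp, srcs in ANCESTRY_GROUPS.items() for src in srcs}
    for src, w in zip(fit.left_set, fit.weights):
        key = assigned.get(src, src)
        grouped[key] = grouped.get(key, 0.0) + float(w)
    return grouped


def _best(fits: list[AdmixtureModelFit], main_group: str) -> AdmixtureModelFit | None:
    """Largest main-group contribution; ties broken by fewer sources,
    then by higher p-value."""
    if not fits:
        return None
    return max(
        fits,
        key=lambda f: (
            grouped_weights(f).get(main_group, 0.0),
            -len(f.left_set),
            f.p_value,
        ),
    )


def select_representative(
    western_fits: list[AdmixtureModelFit],
    eastern_fits: list[AdmixtureModelFit],
    broad_fits: list[AdmixtureModelFit] | None = None,
) -> AdmixtureModelFit | None:
    """Representative model maximizing the main ancestry component.

    Western models compete on Sicilian-Aegean weight, eastern models on
    Levantine weight; when both schemes validate, the larger main
    contribution wins.  Broad-scheme fits are the fallback when neither
    validates; None when no scheme produced a valid fit.
    """
    best_w = _best([f for f in western_fits if f.valid], "SicilianAegean")
    best_e = _best([f for f in eastern_fits if f.valid], "Levant")
    if best_w is not None and best_e is not None:
        main_w = grouped_weights(best_w).get("SicilianAegean", 0.0)
        main_e = grouped_weights(best_e).get("Levant", 0.0)
        if main_w > main_e:
            return best_w
        if main_e > main_w:
            return best_e
        # residual tie: fewer sources, then higher p
        return min(
            (best_w, best_e), key=lambda f: (len(f.left_set), -f.p_value)
        )
    if best_w is not None:
        return best_w
    if best_e is not None:
        return best_e
    if broad_fits:
        valid = [f for f in broad_fits if f.valid]
        if valid:
            return max(valid, key=lambda f: (f.p_value, -len(f.left_set)))
    return None


def min_ancestry(fits: list[AdmixtureModelFit], source: str) -> float | None:
    """Smallest weight of ``source`` over the valid fits (0 when some
    valid fit omits it); None when there is no valid fit."""
    valid = [f for f in fits if f.valid]
    if not valid:
        return None
    return min(f.weight_of(source) for f in valid)


@dataclass
class IndividualModelReport:
    """Per-individual summary of the model search."""

    individual_id: str
    fits: list[AdmixtureModelFit]
    parsimonious_fits: list[AdmixtureModelFit]
    representative: AdmixtureModelFit | None
    min_north_african: float | None

    @property
    def grouped_weights(self) -> dict[str, float] | None:
        return grouped_weights(self.representative) if self.representative else None

    def to_dict(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "n_models": len(self.fits),
            "n_valid": sum(f.valid for f in self.fits),
            "parsimonious": [f.to_dict() for f in self.parsimonious_fits],
            "representative": self.representative.to_dict() if self.representative else None,
            "grouped_weights": self.grouped_weights,
            "min_north_african": self.min_north_african,
        }


def build_report(
    individual_id: str,
    fits_by_scheme: dict[str, list[AdmixtureModelFit]],
    alpha: float = 0.05,
    north_african_source: str = "NorthAfrica_IA",
) -> IndividualModelReport:
    """Run the parsimony filter per scheme and pick the representative."""
    parsimonious = {
        name: parsimony_filter(fits, alpha) for name, fits in fits_by_scheme.items()
    }
    representative = select_representative(
        parsimonious.get("western", []),
        parsimonious.get("eastern", []),
        parsimonious.get("broad", []),
    )
    all_fits = [f for fits in fits_by_scheme.values() for f in fits]
    we_fits = [
        f
        for name in ("western", "eastern")
        for f in fits_by_scheme.get(name, [])
    ] or all_fits
    return IndividualModelReport(
        individual_id=individual_id,
        fits=all_fits,
        parsimonious_fits=[f for fits in parsimonious.values() for f in fits],
        representative=representative,
        min_north_african=min_ancestry(we_fits, north_african_source),
    )
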