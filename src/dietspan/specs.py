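"""Declarative scoring specifications for the five dietary pattern indices.

Each index is a :class:`ScoringSpec`: a list of components, each mapping one
or more intake fields (summed) to points through one of three rules:

``linear``
    Absolute anchors: the ``worst`` anchor earns the component minimum, the
    ``best`` anchor the maximum, linear and clamped in between. Anchors may
    be sex-specific. Direction is implied by anchor order (``worst > best``
    means lower intake is better).
``tent``
    Intermediate-best: full points inside a peak band, declining linearly to
    the band edges' outer anchors. An exact-zero intake may carry its own
    point value (moderate-alcohol components treat never-drinkers separately
    from heavy drinkers).
``quintile``
    Cohort-relative: points follow the quintile of the participant's intake
    within the (optionally sex-stratified) cohort, reversed for adverse
    components.

The shipped defaults encode the canonical published definitions of
AHEI-2010, AMED, hPDI, DASH and DRRD; every anchor and component is
overridable through configuration.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Component",
    "ScoringSpec",
    "default_spec",
    "DEFAULT_SPECS",
    "INDEX_NAMES",
    "ALCOHOL_ADJUSTED_INDICES",
]

INDEX_NAMES = ("AHEI", "AMED", "hPDI", "DASH", "DRRD")

#: Indices without an alcohol component, for which alcohol consumption is an
#: extra covariate in the fully adjusted mortality models.
ALCOHOL_ADJUSTED_INDICES = ("hPDI", "DASH", "DRRD")

Anchors = Dict[str, Tuple[float, float]]  # sex (or "all") -> (worst, best)
TentBand = Dict[str, Tuple[float, float, float, float]]  # lo, peak_lo, peak_hi, hi


class Component(BaseModel):
    name: str
    fields: List[str] = Field(min_length=1)
    rule: Literal["linear", "tent", "quintile"]
    min_points: float
    max_points: float
    # linear rule
    anchors: Optional[Anchors] = None
    # tent rule
    band: Optional[TentBand] = None
    lo_points: Optional[float] = None  # points at/beyond the outer anchors
    zero_points: Optional[float] = None  # override for exact-zero intake
    # quintile rule
    sex_specific: bool = False
    reverse: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.max_points <= self.min_points:
            raise ValueError(f"component {self.name}: max_points <= min_points")
        if self.rule == "linear":
            if not self.anchors:
                raise ValueError(f"component {self.name}: linear rule needs anchors")
            for sex, (worst, best) in self.anchors.items():
                if worst == best:
                    raise ValueError(
                        f"component {self.name} ({sex}): degenerate anchors"
                    )
        if self.rule == "tent":
            if not self.band:
                raise ValueError(f"component {self.name}: tent rule needs band")
            for sex, (lo, p_lo, p_hi, hi) in self.band.items():
                if not (lo <= p_lo <= p_hi <= hi) or lo == hi:
                    raise ValueError(
                        f"component {self.name} ({sex}): band must satisfy "
                        "lo <= peak_lo <= peak_hi <= hi"
                    )
        return self


class ScoringSpec(BaseModel):
    """One dietary index: named components plus its declared total range."""

    name: str
    components: List[Component] = Field(min_length=1)
    range: Tuple[float, float]

    @model_validator(mode="after")
    def _range_closure(self):
        lo = sum(c.min_points for c in self.components)
        hi = sum(c.max_points for c in self.components)
        if (lo, hi) != tuple(self.range):
            raise ValueError(
                f"{self.name}: declared range {self.range} != component-extreme "
                f"sums ({lo}, {hi})"
            )
        return self

    @property
    def field_names(self) -> List[str]:
        out: List[str] = []
        for c in self.components:
            out.extend(c.fields)
        return sorted(set(out))

    def without_component(self, component_name: str) -> "ScoringSpec":
        comps = [c for c in self.components if c.name != component_name]
        if len(comps) == len(self.components):
            raise KeyError(f"{self.name} has no component {component_name!r}")
        lo = sum(c.min_points for c in comps)
        hi = sum(c.max_points for c in comps)
        return ScoringSpec(
            name=f"{self.name}_no_{component_name}", components=comps, range=(lo, hi)
        )


def _lin(name, fields, worst, best, anchors_by_sex=None, lo=0.0, hi=10.0):
    anchors = anchors_by_sex or {"all": (worst, best)}
    return Component(
        name=name, fields=fields, rule="linear", anchors=anchors,
        min_points=lo, max_points=hi,
    )


def _quint(name, fields, reverse=False, sex_specific=False):
    return Component(
        name=name, fields=fields, rule="quintile", reverse=reverse,
        sex_specific=sex_specific, min_points=1, max_points=5,
    )


def _ahei() -> ScoringSpec:
    """AHEI-2010: 11 components, 0-10 points each against absolute anchors.

    Sodium is anchored at the extreme decile medians of the index's source
    cohort (1112 / 3337 mg/day) rather than recomputed cohort deciles, so
    the component is anchor-linear like the others. Alcohol is
    intermediate-best (drinks converted to grams at 14 g/drink):
    never-drinkers earn 2.5 points.
    """
    comps = [
        _lin("vegetables", ["vegetables_srv"], 0.0, 5.0),
        _lin("fruits", ["fruits_srv"], 0.0, 4.0),
        Component(
            name="whole_grains", fields=["whole_grains_g"], rule="linear",
            anchors={"female": (0.0, 75.0), "male": (0.0, 90.0)},
            min_points=0, max_points=10,
        ),
        _lin("ssb_fruit_juice", ["ssb_srv", "fruit_juice_srv"], 1.0, 0.0),
        _lin("nuts_legumes", ["nuts_srv", "legumes_srv"], 0.0, 1.0),
        _lin("red_processed_meat", ["red_meat_srv", "processed_meat_srv"], 1.5, 0.0),
        _lin("trans_fat", ["trans_fat_pct"], 4.0, 0.5),
        _lin("long_chain_n3", ["n3_mg"], 0.0, 250.0),
        _lin("pufa", ["pufa_pct"], 2.0, 10.0),
        _lin("sodium", ["sodium_mg"], 3337.0, 1112.0),
        Component(
            name="alcohol", fields=["alcohol_g"], rule="tent",
            band={"female": (0.0, 7.0, 21.0, 35.0), "male": (0.0, 7.0, 28.0, 49.0)},
            min_points=0, max_points=10, lo_points=2.5, zero_points=2.5,
        ),
    ]
    return ScoringSpec(name="AHEI", components=comps, range=(0, 110))


def _amed() -> ScoringSpec:
    """AMED: 10 components, 1-5 points by sex-specific cohort quintiles.

    Red and processed meat are reverse-scored; alcohol is intermediate-best
    (5-25 g/day earns 5 points) rather than quintile-ranked, since more
    alcohol is never better.
    """
    sx = dict(sex_specific=True)
    comps = [
        _quint("vegetables", ["vegetables_srv"], **sx),
        _quint("legumes", ["legumes_srv"], **sx),
        _quint("fruits", ["fruits_srv"], **sx),
        _quint("nuts", ["nuts_srv"], **sx),
        _quint("whole_grains", ["whole_grains_g"], **sx),
        _quint("fish", ["fish_srv"], **sx),
        _quint("mufa_sfa_ratio", ["mufa_sfa_ratio"], **sx),
        _quint("red_meat", ["red_meat_srv"], reverse=True, **sx),
        _quint("processed_meat", ["processed_meat_srv"], reverse=True, **sx),
        Component(
            name="alcohol", fields=["alcohol_g"], rule="tent",
            band={"all": (0.0, 5.0, 25.0, 40.0)},
            min_points=1, max_points=5,
        ),
    ]
    return ScoringSpec(name="AMED", components=comps, range=(10, 50))


def _hpdi() -> ScoringSpec:
    """hPDI: 17 components, 1-5 points by cohort quintiles; healthy plant
    foods scored positively, less-healthy plant foods and animal foods
    reverse-scored."""
    healthy = [
        ("whole_grains", ["whole_grains_g"]),
        ("fruits", ["fruits_srv"]),
        ("vegetables", ["vegetables_srv"]),
        ("nuts", ["nuts_srv"]),
        ("legumes", ["legumes_srv"]),
        ("vegetable_oils", ["vegetable_oil_srv"]),
        ("tea_coffee", ["tea_coffee_srv"]),
    ]
    adverse = [
        ("fruit_juice", ["fruit_juice_srv"]),
        ("refined_grains", ["refined_grains_g"]),
        ("potatoes", ["potatoes_srv"]),
        ("ssb", ["ssb_srv"]),
        ("sweets_desserts", ["sweets_srv"]),
        ("animal_fat", ["animal_fat_srv"]),
        ("dairy", ["dairy_srv"]),
        ("eggs", ["eggs_srv"]),
        ("fish_seafood", ["fish_srv"]),
        ("meat", ["red_meat_srv", "processed_meat_srv", "poultry_srv"]),
    ]
    comps = [_quint(n, f) for n, f in healthy]
    comps += [_quint(n, f, reverse=True) for n, f in adverse]
    return ScoringSpec(name="hPDI", components=comps, range=(17, 85))


def _dash() -> ScoringSpec:
    """DASH: 8 food groups, 1-5 points by cohort quintiles; sodium, red and
    processed meat, and sugar-sweetened beverages reverse-scored."""
    comps = [
        _quint("fruits", ["fruits_srv"]),
        _quint("vegetables", ["vegetables_srv"]),
        _quint("nuts_legumes", ["nuts_srv", "legumes_srv"]),
        _quint("whole_grains", ["whole_grains_g"]),
        _quint("low_fat_dairy", ["low_fat_dairy_srv"]),
        _quint("sodium", ["sodium_mg"], reverse=True),
        _quint("red_processed_meat", ["red_meat_srv", "processed_meat_srv"],
               reverse=True),
        _quint("ssb", ["ssb_srv"], reverse=True),
    ]
    return ScoringSpec(name="DASH", components=comps, range=(8, 40))


def _drrd() -> ScoringSpec:
    """DRRD: 9 components, 1-5 points by cohort quintiles; includes cereal
    fiber and glycemic index directly; GI, SSB/juice, red and processed
    meat, and trans fat reverse-scored."""
    comps = [
        _quint("cereal_fiber", ["cereal_fiber_g"]),
        _quint("coffee", ["coffee_srv"]),
        _quint("nuts", ["nuts_srv"]),
        _quint("whole_fruits", ["fruits_srv"]),
        _quint("pufa_sfa_ratio", ["pufa_sfa_ratio"]),
        _quint("glycemic_index", ["glycemic_index"], reverse=True),
        _quint("ssb_fruit_juice", ["ssb_srv", "fruit_juice_srv"], reverse=True),
        _quint("red_processed_meat", ["red_meat_srv", "processed_meat_srv"],
               reverse=True),
        _quint("trans_fat", ["trans_fat_pct"], reverse=True),
    ]
    return ScoringSpec(name="DRRD", components=comps, range=(9, 45))


def default_spec(index: str) -> ScoringSpec:
    """Shipped default ScoringSpec for one of the five indices."""
    try:
        return _BUILDERS[index]()
    except KeyError:
        raise KeyError(
            f"unknown dietary index {index!r}; known: {', '.join(INDEX_NAMES)}"
        ) from None


_BUILDERS = {"AHEI": _ahei, "AMED": _amed, "hPDI": _hpdi, "DASH": _dash,
             "DRRD": _drrd}

DEFAULT_SPECS: Dict[str, ScoringSpec] = {name: default_spec(name)
                                         for name in INDEX_NAMES}
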