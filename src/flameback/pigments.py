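"""Carotenoid pigment attributes and concentration-weighted functional-group
statistics.

Plumage carotenoids differ in three largely independent structural
modifications of the beta-carotene backbone: keto groups at carbon C4(4')
(ketolation reddens the pigment), oxygenation at C3(3') (hydroxyl or keto),
and conversion of beta- to epsilon-end rings (which yellows the pigment).
Given per-feather pigment concentrations C_i and per-pigment counts a_i of a
modification, the feather-level prevalence of that modification is the
concentration-weighted mean

    a_bar = sum_i a_i C_i / sum_i C_i

over all identified carotenoids, separately for each of the three elements.

The per-pigment counts are shipped as an editable CSV
(``data/pigment_table.csv``) populated from standard carotenoid structural
formulas, so the statistic stays auditable and correctable. Pigment names
use ASCII spellings (``beta-cryptoxanthin``, ``alpha-doradexanthin``,
``3'-dehydro-lutein``); Greek-letter spellings are normalised on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

ORIGIN_CLASSES = ("dietary_yellow", "metabolised_yellow", "metabolised_red")
ELEMENTS = ("keto_c4", "oxy_c3", "epsilon")
_ELEMENT_COLUMNS = {"keto_c4": "n_keto_c4", "oxy_c3": "n_oxy_c3",
                    "epsilon": "n_epsilon_rings"}


def _normalise_name(name: str) -> str:
    return (name.strip()
            .replace("β", "beta").replace("α", "alpha")
            .replace("′", "'").replace("’", "'")
            .replace("‐", "-").replace("‑", "-").replace("–", "-")
            .lower())


@dataclass(frozen=True)
class Pigment:
    name: str
    n_keto_c4: int
    n_oxy_c3: int
    n_epsilon_rings: int
    origin_class: str

    def __post_init__(self) -> None:
        for attr in ("n_keto_c4", "n_oxy_c3", "n_epsilon_rings"):
            if getattr(self, attr) not in (0, 1, 2):
                raise ValueError(f"{self.name}: {attr} must be in {{0, 1, 2}}")
        if self.origin_class not in ORIGIN_CLASSES:
            raise ValueError(f"{self.name}: unknown origin_class {self.origin_class!r}")

    def count(self, element: str) -> int:
        return getattr(self, _ELEMENT_COLUMNS[element])


@dataclass(frozen=True)
class PigmentTable:
    entries: tuple[Pigment, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pigment names in table")

    def __getitem__(self, name: str) -> Pigment:
        key = _normalise_name(name)
        for p in self.entries:
            if _normalise_name(p.name) == key:
                return p
        raise KeyError(f"pigment {name!r} not in table")

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
        except KeyError:
            return False
        return True

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]


@dataclass(frozen=True)
class PigmentProfile:
    """Per-sample pigment concentrations (single consistent unit, e.g. ug/g)."""

    sample_id: str
    concentrations: dict[str, float]
    feather_region: str = "mantle"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError(f"{self.sample_id}: negative concentration")


@dataclass(frozen=True)
class FunctionalGroupSummary:
    mean_keto_c4: float
    mean_oxy_c3: float
    mean_epsilon: float
    class_totals: dict[str, float] = field(default_factory=dict)
    total_concentration: float = 0.0


def load_pigment_table(path="default") -> PigmentTable:
    """Load a pigment attribute table; ``"default"`` loads the shipped CSV."""
    if path == "default":
        with resources.files("flameback.data").joinpath("pigment_table.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"name", "n_keto_c4", "n_oxy_c3", "n_epsilon_rings", "origin_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pigment table missing columns: {sorted(missing)}")
    entries = tuple(
        Pigment(str(r["name"]), int(r["n_keto_c4"]), int(r["n_oxy_c3"]),
                int(r["n_epsilon_rings"]), str(r["origin_class"]))
        for _, r in df.iterrows()
    )
    return PigmentTable(entries)


def read_profiles(path) -> list[PigmentProfile]:
    """Read profiles from long CSV: sample_id, feather_region, pigment, concentration."""
    df = pd.read_csv(path)
    required = {"sample_id", "pigment", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    if "feather_region" not in df.columns:
        df["feather_region"] = "mantle"
    out = []
    for (sample, region), grp in df.groupby(["sample_id", "feather_region"], sort=True):
        conc = dict(zip(grp["pigment"].astype(str), grp["concentration"].astype(float)))
        out.append(PigmentProfile(str(sample), conc, str(region)))
    return out


def functional_group_mean(profile: PigmentProfile, table: PigmentTable,
                          element: str) -> float:
    """Concentration-weighted mean count of one structural element,
    a_bar = sum(a_i C_i) / sum(C_i) over the profile's pigments."""
    if element not in ELEMENTS:
        raise ValueError(f"unknown element {element!r}; expected one of {ELEMENTS}")
    num = 0.0
    den = 0.0
    for name, conc in profile.concentrations.items():
        if name not in table:
            raise KeyError(f"pigment {name!r} (sample {profile.sample_id}) "
                           f"missing from attribute table")
        num += table[name].count(element) * conc
        den += conc
    if den <= 0:
        raise ValueError(f"{profile.sample_id}: all concentrations zero")
    return num / den


def summarize_profile(profile: PigmentProfile, table: PigmentTable) -> FunctionalGroupSummary:
    """All three weighted means plus per-origin-class and total concentrations."""
    totals = {cls: 0.0 for cls in ORIGIN_CLASSES}
    for name, conc in profile.concentrations.items():
        totals[table[name].origin_class] += conc
    return FunctionalGroupSummary(
        mean_keto_c4=functional_group_mean(profile, table, "keto_c4"),
        mean_oxy_c3=functional_group_mean(profile, table, "oxy_c3"),
        mean_epsilon=functional_group_mean(profile, table, "epsilon"),
        class_totals=totals,
        total_concentration=sum(profile.concentrations.values()),
    )


def profiles_to_table(profiles: list[PigmentProfile], table: PigmentTable) -> pd.DataFrame:
    """Tidy per-sample summary table for downstream group statistics."""
    rows = []
    for p in profiles:
        s = summarize_profile(p, table)
        row = {"sample_id": p.sample_id, "feather_region": p.feather_region,
               "mean_keto_c4": s.mean_keto_c4, "mean_oxy_c3": s.mean_oxy_c3,
               "mean_epsilon": s.mean_epsilon,
               "total_concentration": s.total_concentration}
        row.update({f"total_{cls}": v for cls, v in s.class_totals.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def total_carotenoid_from_absorbance(absorbance_at_peak: float, extract_volume_ml: float,
                                     feather_mass_mg: float,
                                     extinction_coeff: float) -> float:
    """Total carotenoid content (ug per g pigmented feather) by Beer-Lambert.

    ``extinction_coeff`` is the 1%/1cm absorptivity at the absorption peak
    (instrument- and solvent-specific; supplied by the caller).
    Concentration (ug/mL) = A * 1e4 / E(1%,1cm); scaled by extract volume and
    feather mass.
    """
    if extract_volume_ml <= 0 or feather_mass_mg <= 0 or extinction_coeff <= 0:
        raise ValueError("volume, mass and extinction coefficient must be positive")
    if absorbance_at_peak < 0:
        raise ValueError("absorbance must be non-negative")
    conc_ug_per_ml = absorbance_at_peak * 1e4 / extinction_coeff
    total_ug = conc_ug_per_ml * extract_volume_ml
    return total_ug / (feather_mass_mg / 1000.0)
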