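"""Map a combined regimen to a 2014 BTS/SIGN treatment step.

A regimen is a triple (set of drug categories, ICS dose band, OCS mode)
evaluated for an age group.  The mapping is an ordered rule table:
the first matching rule wins, an explicit default catches any treated
regimen no rule names, and validation proves the table total and
deterministic by enumerating the whole finite regimen space.

The shipped default table is a reconstruction of the 2014 BTS/SIGN ladder
structure (the guideline's own drug table is not redistributable):

* step 5 — continuous or frequent oral corticosteroids, regardless of the
  inhaled regimen;
* step 4 — high-dose ICS, or ICS plus two or more add-on controllers
  (LABA, LTRA, theophylline, LAMA);
* step 3 — low-dose ICS plus exactly one add-on controller;
* step 2 — regular preventer: ICS monotherapy, or LTRA/cromone preventer
  monotherapy without ICS;
* step 1 — short-acting reliever only (SABA/SAMA);
* step 0 — diagnosed, no asthma treatment.

Add-on controllers prescribed without ICS (e.g. LABA monotherapy) are real
but guideline-discordant prescribing; they map to step 3 with an anomaly
flag rather than raising.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .config import ConfigError

#: All recognised drug categories (OCS is tracked separately via ocs_mode).
CATEGORIES = ("SABA", "SAMA", "ICS", "LABA", "LAMA", "LTRA",
              "THEOPHYLLINE", "CROMONE", "OCS")

#: Categories that count as add-on controllers alongside ICS.
ADD_ONS = frozenset({"LABA", "LAMA", "LTRA", "THEOPHYLLINE"})
RELIEVERS = frozenset({"SABA", "SAMA"})
#: Non-ICS preventers acceptable as step-2 monotherapy.
ALT_PREVENTERS = frozenset({"LTRA", "CROMONE"})

ICS_BANDS = ("none", "low", "high")
OCS_MODES = ("none", "rescue_only", "continuous")
AGE_GROUPS = ("child", "adult")


@dataclass(frozen=True)
class Regimen:
    categories: frozenset
    ics_dose_band: str   # 'none' | 'low' | 'high'
    ocs_mode: str        # 'none' | 'rescue_only' | 'continuous'

    def n_addons(self) -> int:
        return len(self.categories & ADD_ONS)


@dataclass
class MappingRule:
    """One row of the rule table.

    Conditions are conjunctive; ``None``/empty means "any".  ``n_addons``
    is an (op, value) pair with op in {'==', '>=', '<='} counting add-on
    controllers present.
    """

    name: str
    step: int
    anomaly: bool = False
    ocs_mode: tuple[str, ...] | None = None
    ics_band: tuple[str, ...] | None = None
    has_ics: bool | None = None
    n_addons: tuple[str, int] | None = None
    requires_any: frozenset = frozenset()
    only_from: frozenset | None = None   # categories must be a subset of this

    def matches(self, reg: Regimen, age_group: str) -> bool:
        if self.ocs_mode is not None and reg.ocs_mode not in self.ocs_mode:
            return False
        if self.ics_band is not None and reg.ics_dose_band not in self.ics_band:
            return False
        if self.has_ics is not None and ("ICS" in reg.categories) != self.has_ics:
            return False
        if self.n_addons is not None:
            op, val = self.n_addons
            n = reg.n_addons()
            ok = {"==": n == val, ">=": n >= val, "<=": n <= val}[op]
            if not ok:
                return False
        if self.requires_any and not (reg.categories & self.requires_any):
            return False
        if self.only_from is not None and not reg.categories <= self.only_from:
            return False
        return True

    def to_dict(self) -> dict:
        d = {"name": self.name, "step": self.step, "anomaly": self.anomaly}
        if self.ocs_mode is not None:
            d["ocs_mode"] = list(self.ocs_mode)
        if self.ics_band is not None:
            d["ics_band"] = list(self.ics_band)
        if self.has_ics is not None:
            d["has_ics"] = self.has_ics
        if self.n_addons is not None:
            d["n_addons"] = list(self.n_addons)
        if self.requires_any:
            d["requires_any"] = sorted(self.requires_any)
        if self.only_from is not None:
            d["only_from"] = sorted(self.only_from)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MappingRule":
        kw = dict(d)
        for key in ("ocs_mode", "ics_band"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        if kw.get("n_addons") is not None:
            op, val = kw["n_addons"]
            kw["n_addons"] = (op, int(val))
        if "requires_any" in kw:
            kw["requires_any"] = frozenset(kw["requires_any"])
        if kw.get("only_from") is not None:
            kw["only_from"] = frozenset(kw["only_from"])
        return cls(**kw)


@dataclass
class StepMappingConfig:
    """Ordered rule list plus a default step for unmatched treated regimens."""

    rules: list[MappingRule] = field(default_factory=list)
    default_step: int = 1
    default_anomaly: bool = True

    def to_dict(self) -> dict:
        return {"rules": [r.to_dict() for r in self.rules],
                "default_step": self.default_step,
                "default_anomaly": self.default_anomaly}

    @classmethod
    def from_dict(cls, d: dict) -> "StepMappingConfig":
        return cls(rules=[MappingRule.from_dict(r) for r in d["rules"]],
                   default_step=int(d.get("default_step", 1)),
                   default_anomaly=bool(d.get("default_anomaly", True)))


def default_mapping() -> StepMappingConfig:
    """The shipped reconstruction of the 2014 BTS/SIGN step table."""
    rules = [
        MappingRule("continuous-ocs", step=5,
                    ocs_mode=("continuous",)),
        MappingRule("high-dose-ics", step=4,
                    ics_band=("high",)),
        MappingRule("ics-two-addons", step=4,
                    has_ics=True, n_addons=(">=", 2)),
        MappingRule("ics-one-addon", step=3,
                    has_ics=True, n_addons=("==", 1)),
        MappingRule("ics-monotherapy", step=2,
                    has_ics=True, n_addons=("==", 0)),
        MappingRule("alt-preventer", step=2,
                    has_ics=False, requires_any=ALT_PREVENTERS,
                    only_from=ALT_PREVENTERS | RELIEVERS),
        MappingRule("addon-without-ics", step=3, anomaly=True,
                    has_ics=False, requires_any=ADD_ONS),
        MappingRule("reliever-only", step=1,
                    has_ics=False, requires_any=RELIEVERS,
                    only_from=RELIEVERS),
        MappingRule("untreated", step=0,
                    only_from=frozenset(), ocs_mode=("none",)),
    ]
    return StepMappingConfig(rules=rules, default_step=1, default_anomaly=True)


def map_regimen_to_step(categories, ics_dose_band: str, ocs_mode: str,
                        age_group: str,
                        mapping: StepMappingConfig | None = None,
                        ) -> tuple[int, bool]:
    """Return ``(step, anomaly_flag)`` for one regimen; first match wins."""
    if mapping is None:
        mapping = default_mapping()
    reg = Regimen(frozenset(categories) - {"OCS"}, ics_dose_band, ocs_mode)
    for rule in mapping.rules:
        if rule.matches(reg, age_group):
            return rule.step, rule.anomaly
    return mapping.default_step, mapping.default_anomaly


def enumerate_regimen_space():
    """Yield every (categories, ics_band, ocs_mode, age_group) combination.

    The space is finite: all subsets of the non-OCS categories, with the
    structural constraint that the ICS band is 'none' exactly when ICS is
    absent.
    """
    cats = [c for c in CATEGORIES if c != "OCS"]
    for r in range(len(cats) + 1):
        for combo in itertools.combinations(cats, r):
            cset = frozenset(combo)
            bands = ("low", "high") if "ICS" in cset else ("none",)
            for band in bands:
                for mode in OCS_MODES:
                    for group in AGE_GROUPS:
                        yield cset, band, mode, group


def validate_mapping(mapping: StepMappingConfig) -> list[str]:
    """Exhaustively check totality and determinism; return error strings.

    An empty rule list is rejected outright.  Rules that can never fire
    because an earlier rule shadows them are reported (as notes, not
    errors, since first-match semantics stays well defined).
    """
    errors: list[str] = []
    if not mapping.rules:
        return ["empty rule list"]
    if not (0 <= mapping.default_step <= 5):
        errors.append(f"default_step {mapping.default_step} outside 0..5")
    for r in mapping.rules:
        if not (0 <= r.step <= 5):
            errors.append(f"rule {r.name!r}: step {r.step} outside 0..5")
    fired = [False] * len(mapping.rules)
    for cset, band, mode, group in enumerate_regimen_space():
        reg = Regimen(cset, band, mode)
        for i, rule in enumerate(mapping.rules):
            if rule.matches(reg, group):
                fired[i] = True
                break
    for i, rule in enumerate(mapping.rules):
        if not fired[i]:
            errors.append(f"note: rule {rule.name!r} is shadowed (never first match)")
    return errors


def mapping_truth_table(mapping: StepMappingConfig | None = None) -> pd.DataFrame:
    """The effective step for every regimen in the space, one row each."""
    if mapping is None:
        mapping = default_mapping()
    rows = []
    for cset, band, mode, group in enumerate_regimen_space():
        step, anomaly = map_regimen_to_step(cset, band, mode, group, mapping)
        rows.append({"categories": "|".join(sorted(cset)) or "(none)",
                     "ics_dose_band": band, "ocs_mode": mode,
                     "age_group": group, "step": step, "anomaly": anomaly})
    return pd.DataFrame(rows)


def assert_valid_mapping(mapping: StepMappingConfig) -> None:
    errs = [e for e in validate_mapping(mapping) if not e.startswith("note:")]
    if errs:
        raise ConfigError("invalid step mapping: " + "; ".join(errs))
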