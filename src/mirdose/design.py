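"""Cohort study design: dose groups, sexes, timepoints, survival outcome.

The default design mirrors a 36-animal rhesus macaque total-body irradiation
cohort: six dose groups from 6.0 to 8.5 Gy in 0.5 Gy steps, six animals per
group, serum sampled pre-irradiation and on days 1, 2 and 6 post-irradiation.
Survival ("RRiF", risk of radiation-induced fatality) is scored per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ordered timepoint labels; "pre" is the pre-irradiation baseline.
TIMEPOINTS = ("pre", "d1", "d2", "d6")

#: Days since irradiation for each post-irradiation timepoint.
TIMEPOINT_DAYS = {"d1": 1, "d2": 2, "d6": 6}


@dataclass(frozen=True)
class DoseGroup:
    """One irradiation group: dose, size, sex split and survivor count."""

    dose_gy: float
    n_animals: int
    n_male: int
    n_female: int
    n_survived: int

    def validate(self) -> None:
        if self.n_animals <= 0:
            raise ValueError(f"group at {self.dose_gy} Gy has non-positive size")
        if self.n_male + self.n_female != self.n_animals:
            raise ValueError(
                f"group at {self.dose_gy} Gy: sexes ({self.n_male}M/{self.n_female}F) "
                f"do not sum to {self.n_animals}"
            )
        if not 0 <= self.n_survived <= self.n_animals:
            raise ValueError(
                f"group at {self.dose_gy} Gy: survivors {self.n_survived} outside "
                f"[0, {self.n_animals}]"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Dose groups plus the ordered sampling timepoints."""

    groups: tuple[DoseGroup, ...]
    timepoints: tuple[str, ...] = TIMEPOINTS

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("design has no dose groups")
        for g in self.groups:
            g.validate()
        if len({g.dose_gy for g in self.groups}) != len(self.groups):
            raise ValueError("duplicate dose groups")
        if self.timepoints[0] != "pre":
            raise ValueError("first timepoint must be the pre-irradiation baseline")

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.groups)

    @property
    def n_samples(self) -> int:
        return self.n_animals * len(self.timepoints)


def default_design() -> StudyDesign:
    """The 36-animal, six-dose reference cohort.

    19 males and 17 females over six groups of six. Ten of the 18 animals at
    6.0-7.0 Gy survived, six of the 18 at 7.5-8.5 Gy; survivors decrease
    monotonically with dose.
    """
    rows = [
        # dose, n, male, female, survived
        (6.0, 6, 4, 2, 4),
        (6.5, 6, 3, 3, 3),
        (7.0, 6, 3, 3, 3),
        (7.5, 6, 3, 3, 3),
        (8.0, 6, 3, 3, 2),
        (8.5, 6, 3, 3, 1),
    ]
    design = StudyDesign(tuple(DoseGroup(*r) for r in rows))
    design.validate()
    return design


def cohort_survival_summary(design: StudyDesign, dose_cut: float = 7.0) -> dict:
    """Survivor counts and whole-percent survival rates by dose stratum.

    Strata: doses <= ``dose_cut``, doses > ``dose_cut``, and overall.
    Rates are ``100 * survivors / stratum size`` rounded to the nearest
    whole percent.
    """
    design.validate()

    def _stratum(groups):
        n = sum(g.n_animals for g in groups)
        s = sum(g.n_survived for g in groups)
        return {
            "n_animals": n,
            "n_survived": s,
            "rate_pct": round(100.0 * s / n) if n else 0,
        }

    low = [g for g in design.groups if g.dose_gy <= dose_cut]
    high = [g for g in design.groups if g.dose_gy > dose_cut]
    return {
        "low_dose": _stratum(low),
        "high_dose": _stratum(high),
        "overall": _stratum(design.groups),
        "dose_cut_gy": dose_cut,
    }
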