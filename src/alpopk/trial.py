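"""Synthetic phase-2A-like trial generation and the tabular event format.

The original concentration data are not public, so this module generates
stand-in datasets that emulate the study design: a 1,000-mg once-daily arm
sampled on day 1 and a titration arm (1,000 -> 1,500 -> 2,000 mg) sampled
on days 14 and 28, with 12 blood draws per sampling occasion at
0, 0.25, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6 and 8 h post-dose.

Datasets use a NONMEM-dialect CSV: one row per event, columns

    ID, OCC, TIME, AMT, DV, EVID, MDV, FLOOR, SEX, AGE, WT, HT

where EVID 1 marks a dose row (AMT in mg, MDV 1) and EVID 0 an observation
row (DV in mg/L).  OCC tags the study occasion (day1/day14/day28) and TIME is
hours within that occasion, with the occasion's dose at TIME 0.  FLOOR flags
observations whose simulated value was negative before being floored at 0.
Covariates (SEX, AGE, WT, HT) are drawn from plausible synthetic
distributions and — matching the study's finding of no influential
covariate — carry no effect on the PK parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import pk
from .population import PopulationModel, residual_sd, sample_param_arrays

__all__ = [
    "STANDARD_SAMPLING_TIMES",
    "CovariateGenerators",
    "Arm",
    "TrialDesign",
    "Dataset",
    "default_design",
    "generate_trial",
    "read_dataset",
    "write_dataset",
]

#: blood-sampling schedule on a PK day, hours post-dose
STANDARD_SAMPLING_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0)

COLUMNS = ["ID", "OCC", "TIME", "AMT", "DV", "EVID", "MDV", "FLOOR", "SEX", "AGE", "WT", "HT"]


@dataclass(frozen=True)
class CovariateGenerators:
    """Synthetic demographic distributions (no demographics table exists for
    the cohort; these are invented but plausible defaults for the population)."""

    age_mean: float = 63.0
    age_sd: float = 8.0
    weight_mean: float = 58.0
    weight_sd: float = 9.0
    height_mean: float = 160.0
    height_sd: float = 8.0
    p_male: float = 0.5

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SEX": rng.binomial(1, self.p_male, n),
                "AGE": np.clip(rng.normal(self.age_mean, self.age_sd, n), 18, 95).round(1),
                "WT": np.clip(rng.normal(self.weight_mean, self.weight_sd, n), 30, 120).round(1),
                "HT": np.clip(rng.normal(self.height_mean, self.height_sd, n), 130, 200).round(1),
            }
        )


@dataclass(frozen=True)
class Arm:
    """One treatment arm: subjects, daily dose schedule and PK sampling days.

    ``dose_mg_by_day`` maps an inclusive day range ``(first, last)`` to the
    once-daily dose in mg; ``pk_days`` maps a sampling day to its occasion
    label (which selects the occasion's population model).
    """

    name: str
    n_subjects: int
    dose_mg_by_day: tuple[tuple[int, int, float], ...]
    pk_days: tuple[tuple[int, str], ...]

    def dose_on_day(self, day: int) -> float:
        for first, last, dose in self.dose_mg_by_day:
            if first <= day <= last:
                return dose
        raise ValueError(f"day {day} outside the dosing schedule of arm {self.name!r}")


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple[Arm, ...]
    sampling_times: tuple[float, ...] = STANDARD_SAMPLING_TIMES
    covariates: CovariateGenerators = field(default_factory=CovariateGenerators)

    def __post_init__(self) -> None:
        st = self.sampling_times
        if len(st) == 0 or st[0] != 0.0:
            raise ValueError("sampling times must start at 0")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("sampling times must be strictly increasing")
        for arm in self.arms:
            if arm.n_subjects < 1:
                raise ValueError(f"arm {arm.name!r} must have >= 1 subject")


def default_design() -> TrialDesign:
    """The study design: 15 subjects at 1,000 mg sampled on day 1, and 16
    titration subjects (1,000/1,500/2,000 mg) sampled on days 14 and 28."""
    group1 = Arm(
        name="group1",
        n_subjects=15,
        dose_mg_by_day=((1, 90, 1000.0),),
        pk_days=((1, "day1"),),
    )
    group2 = Arm(
        name="group2",
        n_subjects=16,
        dose_mg_by_day=((1, 14, 1000.0), (15, 28, 1500.0), (29, 90, 2000.0)),
        pk_days=((14, "day14"), (28, "day28")),
    )
    return TrialDesign(arms=(group1, group2))


class Dataset:
    """A table of dosing and observation events (see module docstring)."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def occasions(self) -> list[str]:
        return list(self.df["OCC"].unique())

    def observations(self, occasion: str | None = None) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        return obs if occasion is None else obs[obs["OCC"] == occasion]

    def doses(self, occasion: str | None = None) -> pd.DataFrame:
        dose = self.df[self.df["EVID"] == 1]
        return dose if occasion is None else dose[dose["OCC"] == occasion]

    def covariates(self) -> pd.DataFrame:
        """One row per subject."""
        return (
            self.df.groupby("ID")[["SEX", "AGE", "WT", "HT"]].first().reset_index()
        )

    def validate(self) -> None:
        df = self.df
        unknown = [c for c in df.columns if c not in COLUMNS]
        if unknown:
            raise ValueError(f"unknown columns: {unknown}")
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not set(df["EVID"].unique()) <= {0, 1}:
            bad = df.index[~df["EVID"].isin([0, 1])][0]
            raise ValueError(f"row {bad + 2}: EVID must be 0 or 1")
        obs = df["EVID"] == 0
        neg = obs & (df["DV"] < 0)
        if neg.any():
            raise ValueError(
                f"row {df.index[neg][0] + 2}: negative concentration {df.loc[df.index[neg][0], 'DV']}"
            )
        dose_rows = df[df["EVID"] == 1]
        if (dose_rows["MDV"] != 1).any():
            bad = dose_rows.index[dose_rows["MDV"] != 1][0]
            raise ValueError(f"row {bad + 2}: dose rows must have MDV=1")
        for (sid, occ), grp in df.groupby(["ID", "OCC"], sort=False):
            if not (grp["EVID"] == 1).any():
                raise ValueError(f"subject {sid} occasion {occ}: no dose row")
            times = grp.loc[grp["EVID"] == 0, "TIME"].to_numpy()
            if np.any(np.diff(times) <= 0):
                i = grp.index[grp["EVID"] == 0][int(np.argmax(np.diff(times) <= 0)) + 1]
                raise ValueError(
                    f"row {i + 2}: observation times not strictly increasing "
                    f"for subject {sid} occasion {occ}"
                )
            first_dose = grp.loc[grp["EVID"] == 1, "TIME"].min()
            pre = grp[(grp["EVID"] == 0) & (grp["TIME"] < first_dose) & (grp["DV"] > 0)]
            if len(pre):
                warnings.warn(
                    f"subject {sid} occasion {occ}: positive concentration "
                    f"before the first dose (pre-dose contamination?)",
                    UserWarning,
                    stacklevel=2,
                )


def generate_trial(
    design: TrialDesign,
    pop_by_occasion: Mapping[str, PopulationModel],
    seed,
) -> Dataset:
    """Simulate a trial dataset.

    Per subject and sampling occasion: draw a fresh random-effect triple from
    that occasion's population model, evaluate the true single-dose profile at
    the design sampling times (the drug's short half-life makes carry-over
    from earlier daily doses negligible, < 1e-5 of Cmax), then add combined
    residual error, flooring negative draws at 0 with a flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    needed = {occ for arm in design.arms for _, occ in arm.pk_days}
    missing = needed - set(pop_by_occasion)
    if missing:
        raise ValueError(f"no population model assigned for occasion(s) {sorted(missing)}")

    times = np.asarray(design.sampling_times)
    rows: list[pd.DataFrame] = []
    next_id = 1
    for arm in design.arms:
        cov = design.covariates.draw(arm.n_subjects, rng)
        ids = np.arange(next_id, next_id + arm.n_subjects)
        next_id += arm.n_subjects
        for day, occ in arm.pk_days:
            pop = pop_by_occasion[occ]
            dose = arm.dose_on_day(day)
            _, params = sample_param_arrays(pop, arm.n_subjects, rng)
            tk0, v, cl = params[:, 0], params[:, 1], params[:, 2]
            ke = cl / v
            f = pk._single_dose(
                tk0[:, None], ke[:, None], cl[:, None], dose, times[None, :]
            )
            y = f + residual_sd(pop, f) * rng.standard_normal(f.shape)
            floored = y < 0
            y = np.where(floored, 0.0, y)
            for i, sid in enumerate(ids):
                block = pd.DataFrame(
                    {
                        "ID": sid,
                        "OCC": occ,
                        "TIME": np.concatenate([[0.0], times]),
                        "AMT": np.concatenate([[dose], np.zeros(times.size)]),
                        "DV": np.concatenate([[0.0], y[i]]),
                        "EVID": np.concatenate([[1], np.zeros(times.size, dtype=int)]),
                        "MDV": np.concatenate([[1], np.zeros(times.size, dtype=int)]),
                        "FLOOR": np.concatenate([[0], floored[i].astype(int)]),
                    }
                )
                for c in ("SEX", "AGE", "WT", "HT"):
                    block[c] = cov.loc[i, c]
                rows.append(block)
    df = pd.concat(rows, ignore_index=True)
    df = df.astype({"ID": int, "EVID": int, "MDV": int, "FLOOR": int, "SEX": int})
    return Dataset(df[COLUMNS])


def _broadcast_single_dose_conc(tk0, v, cl, dose, times):
    """True concentrations for per-subject params at shared times (n, m)."""
    ke = np.asarray(cl) / np.asarray(v)
    return pk._single_dose(
        np.asarray(tk0)[:, None], ke[:, None], np.asarray(cl)[:, None],
        dose, np.asarray(times)[None, :],
    )


def write_dataset(dataset: Dataset, path) -> None:
    dataset.df.to_csv(path, index=False)  # default float repr round-trips exactly


def read_dataset(path) -> Dataset:
    """Read and strictly validate a dataset CSV (errors name the file row)."""
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"could not read dataset {path}: {exc}") from exc
    return Dataset(df)
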