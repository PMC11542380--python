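"""Between-subject variability and residual error.

Each structural parameter (tk0, v, cl) carries a random effect.  Two
conventions are supported per parameter:

* ``lognormal`` — the parameter is normal on the log scale:
  ``p_i = typical * exp(eta)`` with ``eta ~ N(0, omega^2)``; the implied
  coefficient of variation is ``100*sqrt(exp(omega^2) - 1)`` %.
* ``normal`` — the parameter is normal on the natural scale:
  ``p_i = typical + eta``; implied CV is ``100*omega/typical`` %.

The printed dispersion columns of the three study-occasion parameter tables
are mutually consistent only under a mixed convention: tk0 and cl are
lognormal on every occasion, while v is normal on day 1 and day 14 and
lognormal on day 28.  The bundled presets encode exactly that.

Residual (within-subject) error is the combined additive + proportional model

    y = f + g(f) * eps,   eps ~ N(0, 1)

with ``g(f) = a + b*f`` by default ("combined-1") or
``g(f) = sqrt(a^2 + (b*f)^2)`` ("combined-2") behind a switch, since the
source tables report only the two coefficients, not the variant.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .pk import StructuralParams

__all__ = [
    "ParameterDistribution",
    "PopulationModel",
    "VirtualPatient",
    "individual_params",
    "sample_patients",
    "sample_param_arrays",
    "implied_cv",
    "residual_sd",
    "residual_observe",
    "PRESETS",
    "PRINTED_CV",
    "get_preset",
    "zero_variability",
]

Kind = Literal["lognormal", "normal"]
ErrorForm = Literal["combined1", "combined2"]

_MAX_TRUNCATION_RETRIES = 1000


@dataclass(frozen=True)
class ParameterDistribution:
    """Population distribution of one structural parameter.

    ``omega`` is the random-effect SD: on the log scale for ``lognormal``
    kind, in the parameter's own units for ``normal`` kind.
    """

    typical: float
    omega: float
    kind: Kind = "lognormal"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.typical) and self.typical > 0):
            raise ValueError(f"typical must be finite and > 0, got {self.typical!r}")
        if not (math.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be finite and >= 0, got {self.omega!r}")
        if self.kind not in ("lognormal", "normal"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, random-effect SDs and residual error for one occasion."""

    tk0: ParameterDistribution
    v: ParameterDistribution
    cl: ParameterDistribution
    err_a: float
    err_b: float
    label: str = ""
    error_form: ErrorForm = "combined1"

    def __post_init__(self) -> None:
        if self.err_a < 0 or self.err_b < 0:
            raise ValueError("residual error parameters must be >= 0")
        if self.error_form not in ("combined1", "combined2"):
            raise ValueError(f"unknown error_form {self.error_form!r}")

    @property
    def typical_params(self) -> StructuralParams:
        return StructuralParams(self.tk0.typical, self.v.typical, self.cl.typical)

    def distributions(self) -> tuple[ParameterDistribution, ParameterDistribution, ParameterDistribution]:
        return (self.tk0, self.v, self.cl)

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {"label": self.label, "error_form": self.error_form,
             "err_a": self.err_a, "err_b": self.err_b}
        for name, dist in zip(("tk0", "v", "cl"), self.distributions()):
            d[name] = {"typical": dist.typical, "omega": dist.omega, "kind": dist.kind}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModel":
        dists = {}
        for name in ("tk0", "v", "cl"):
            spec = d[name]
            dists[name] = ParameterDistribution(
                float(spec["typical"]), float(spec["omega"]), spec["kind"]
            )
        return cls(
            tk0=dists["tk0"], v=dists["v"], cl=dists["cl"],
            err_a=float(d["err_a"]), err_b=float(d["err_b"]),
            label=str(d.get("label", "")), error_form=d.get("error_form", "combined1"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PopulationModel":
        """Load from a YAML file path or a YAML string."""
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(source))


@dataclass(frozen=True)
class VirtualPatient:
    """A sampled individual: random-effect vector and resulting parameters."""

    id: int
    eta: np.ndarray  # (tk0, v, cl) random effects
    params: StructuralParams


def implied_cv(dist: ParameterDistribution) -> float:
    """Coefficient of variation (%) implied by a parameter distribution."""
    if dist.omega == 0:
        return 0.0
    if dist.kind == "lognormal":
        return 100.0 * math.sqrt(math.expm1(dist.omega**2))
    return 100.0 * dist.omega / dist.typical


def individual_params(pop: PopulationModel, eta: Sequence[float]) -> StructuralParams:
    """Map a random-effect triple to individual structural parameters.

    Raises ``ValueError`` if a normal-kind effect pushes a parameter to or
    below zero (callers sampling etas must resample instead of clipping).
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 3-vector")
    values = []
    for dist, e in zip(pop.distributions(), eta):
        if dist.kind == "lognormal":
            values.append(dist.typical * math.exp(e))
        else:
            p = dist.typical + e
            if p <= 0:
                raise ValueError(
                    f"normal-kind random effect {e} drives parameter "
                    f"(typical {dist.typical}) non-positive"
                )
            values.append(p)
    return StructuralParams(*values)


def sample_param_arrays(
    pop: PopulationModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sampling: returns ``(etas (n,3), params (n,3))``.

    Normal-kind draws that land non-positive are rejected and redrawn (never
    clipped); more than 1000 consecutive all-rejected rounds is a hard error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    etas = np.empty((n, 3))
    params = np.empty((n, 3))
    for j, dist in enumerate(pop.distributions()):
        e = rng.normal(0.0, dist.omega, size=n)
        if dist.kind == "normal":
            bad = dist.typical + e <= 0
            tries = 0
            while np.any(bad):
                tries += 1
                if tries > _MAX_TRUNCATION_RETRIES:
                    raise RuntimeError(
                        f"could not draw positive normal-kind parameter after "
                        f"{_MAX_TRUNCATION_RETRIES} retries (typical "
                        f"{dist.typical}, omega {dist.omega})"
                    )
                e[bad] = rng.normal(0.0, dist.omega, size=int(bad.sum()))
                bad = dist.typical + e <= 0
            params[:, j] = dist.typical + e
        else:
            params[:, j] = dist.typical * np.exp(e)
        etas[:, j] = e
    return etas, params


def sample_patients(pop: PopulationModel, n: int, seed) -> list[VirtualPatient]:
    """Draw ``n`` virtual patients with independent diagonal random effects."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    etas, params = sample_param_arrays(pop, n, rng)
    return [
        VirtualPatient(i, etas[i].copy(), StructuralParams(*params[i]))
        for i in range(n)
    ]


def residual_sd(pop: PopulationModel, f: np.ndarray | float) -> np.ndarray | float:
    """SD of the residual error at true concentration ``f``."""
    if pop.error_form == "combined1":
        return pop.err_a + pop.err_b * np.asarray(f, dtype=float)
    return np.sqrt(pop.err_a**2 + (pop.err_b * np.asarray(f, dtype=float)) ** 2)


def residual_observe(
    true_conc: np.ndarray | float, pop: PopulationModel, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Add combined residual error; negative results are floored at 0.

    Returns ``(observed, floored_flag)`` — the flag records which draws were
    negative before flooring (the synthetic datasets keep them at 0 rather
    than dropping them, since no below-quantification rule is specified).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.asarray(true_conc, dtype=float)
    if np.any(f < 0):
        raise ValueError("true concentrations must be >= 0")
    y = f + residual_sd(pop, f) * rng.standard_normal(f.shape)
    floored = y < 0
    return np.where(floored, 0.0, y), floored


# ---------------------------------------------------------------------------
# Bundled occasion presets (study day 1, day 14, day 28 parameter tables).
# ---------------------------------------------------------------------------

PRESETS: dict[str, PopulationModel] = {
    "table1_day1": PopulationModel(
        tk0=ParameterDistribution(0.85, 0.51, "lognormal"),
        v=ParameterDistribution(42.82, 13.2, "normal"),
        cl=ParameterDistribution(20.9, 0.54, "lognormal"),
        err_a=0.36, err_b=0.32, label="day1",
    ),
    "table2_day14": PopulationModel(
        tk0=ParameterDistribution(1.11, 0.35, "lognormal"),
        v=ParameterDistribution(32.57, 8.89, "normal"),
        cl=ParameterDistribution(17.2, 0.44, "lognormal"),
        err_a=1.39, err_b=0.17, label="day14",
    ),
    "table3_day28": PopulationModel(
        tk0=ParameterDistribution(0.95, 0.28, "lognormal"),
        v=ParameterDistribution(32.0, 0.25, "lognormal"),
        cl=ParameterDistribution(16.13, 0.38, "lognormal"),
        err_a=2.21, err_b=0.084, label="day28",
    ),
}

#: printed %CV values for the nine omega rows, used by diagnostics/tests
PRINTED_CV = {
    "table1_day1": {"tk0": 54.88, "v": 30.82, "cl": 57.91},
    "table2_day14": {"tk0": 36.57, "v": 27.3, "cl": 46.6},
    "table3_day28": {"tk0": 28.3, "v": 25.03, "cl": 38.92},
}


def get_preset(name: str) -> PopulationModel:
    """Return a bundled occasion model by preset name or occasion label."""
    if name in PRESETS:
        return PRESETS[name]
    for model in PRESETS.values():
        if model.label == name:
            return model
    raise KeyError(f"unknown population-model preset {name!r}; "
                   f"available: {sorted(PRESETS)} or labels day1/day14/day28")


def zero_variability(pop: PopulationModel) -> PopulationModel:
    """Copy of ``pop`` with all omegas and residual error set to zero."""
    return replace(
        pop,
        tk0=replace(pop.tk0, omega=0.0),
        v=replace(pop.v, omega=0.0),
        cl=replace(pop.cl, omega=0.0),
        err_a=0.0, err_b=0.0,
    )
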