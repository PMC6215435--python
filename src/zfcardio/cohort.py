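"""End-to-end cohort runs: simulate groups of individuals, measure each one
with the full pipeline, and compare groups per metric.

This mirrors a wild-type vs mutant screen: each group carries one base
parameter set (its phenotype), each individual gets its own RNG seed
(``base_seed + running index``) plus an optional multiplicative biological
jitter, and every measured metric is compared between the first two groups
with the normality-gated test policy. Re-running the same spec reproduces
every number bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import cardiac, flow, vessels
from .errors import CohortError, ZfCardioError
from .simulate import (
    FlowSimParams,
    HeartSimParams,
    VesselSimParams,
    simulate_flow_video,
    simulate_heart_video,
    simulate_vessel_stack,
)
from .stats import GroupComparison, compare_groups

__all__ = ["GroupSpec", "CohortSpec", "CohortResult", "run_cohort"]

CARDIAC_METRICS = ["hr_bpm", "edv", "esv", "sv", "co", "sf_pct", "ef_pct", "fac_pct"]


@dataclass(frozen=True)
class GroupSpec:
    """One phenotype group: a label, a size and its simulation parameters."""

    label: str
    n: int
    heart: HeartSimParams | None = None
    flow: FlowSimParams | None = None
    vessel: VesselSimParams | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise CohortError(f"group {self.label!r}: need n >= 3, got {self.n}")
        if self.heart is None and self.flow is None and self.vessel is None:
            raise CohortError(f"group {self.label!r}: no simulation parameters given")


@dataclass(frozen=True)
class CohortSpec:
    """A whole cohort: ≥ 2 groups, a base seed and the biological jitter.

    ``param_cv`` is the coefficient of variation of the per-individual
    factors (truncated at ±3 cv) emulating between-animal variability along
    the natural axes: overall heart size, heart rate, contractility (the
    systolic-to-diastolic axis ratio), flow velocity and vessel radii; 0
    disables all of them.
    """

    groups: tuple[GroupSpec, ...]
    base_seed: int = 0
    param_cv: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) < 2:
            raise CohortError("need at least 2 groups")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise CohortError(f"group labels must be unique, got {labels}")
        if not 0 <= self.param_cv < 0.3:
            raise CohortError("param_cv must lie in [0, 0.3)")


@dataclass
class CohortResult:
    table: pd.DataFrame                       # one row per individual
    comparisons: dict[str, GroupComparison]   # metric → first-vs-second group
    failures: list[dict]                      # recorded per-individual errors
    provenance: dict                          # resolved parameters and seeds


def _jitter_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    f = 1.0 + cv * rng.standard_normal()
    return float(np.clip(f, 1.0 - 3 * cv, 1.0 + 3 * cv))


def _individual_params(group: GroupSpec, seed: int, cv: float):
    """Per-individual parameter sets: jittered copies with their own seed."""
    rng = np.random.default_rng(seed)
    out = {}
    if group.heart is not None:
        s = _jitter_factor(rng, cv)       # overall heart size
        hr_f = _jitter_factor(rng, cv)    # heart rate
        q = _jitter_factor(rng, cv)       # contractility: scales systolic axes
        p = group.heart
        # systolic axes stay below the diastolic ones
        q = min(q, 0.999 * p.a_d / p.a_s, 0.999 * p.b_d / p.b_s)
        out["heart"] = replace(
            p, seed=seed,
            a_d=p.a_d * s, b_d=p.b_d * s, a_s=p.a_s * s * q, b_s=p.b_s * s * q,
            heart_rate=p.heart_rate * hr_f,
        )
    if group.flow is not None:
        v_f = _jitter_factor(rng, cv)
        out["flow"] = replace(group.flow, seed=seed, velocity=group.flow.velocity * v_f)
    if group.vessel is not None:
        r_f = _jitter_factor(rng, cv)
        p = group.vessel
        out["vessel"] = replace(
            p, seed=seed, ring_radius=p.ring_radius * r_f, tube_radius=p.tube_radius * r_f
        )
    return out


def _measure_individual(params: dict) -> dict:
    row: dict[str, float] = {}
    if "heart" in params:
        video, _gt = simulate_heart_video(params["heart"])
        rep = cardiac.cardiac_report(video)
        for m in CARDIAC_METRICS:
            row[m] = getattr(rep, m)
    if "flow" in params:
        video, _gt = simulate_flow_video(params["flow"])
        rep = flow.flow_report(video, mode=params["flow"].mode)
        row["flow_velocity"] = rep.mean_velocity
    if "vessel" in params:
        stack, _gt = simulate_vessel_stack(params["vessel"])
        binary = vessels.segment_vessels(stack)
        selected = vessels.select_structure(binary)
        row["vessel_volume"] = vessels.vessel_volume(selected).volume
    return row


def run_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate, measure and compare a whole cohort.

    Individuals are seeded ``base_seed + running index`` across groups. A
    pipeline error aborts only that individual and is recorded; the cohort
    fails if any group drops below n = 3 measured individuals. Group
    comparisons are computed metric-wise between the first two groups.
    """
    rows = []
    failures = []
    provenance: dict = {"base_seed": spec.base_seed, "param_cv": spec.param_cv, "individuals": []}
    idx = 0
    for group in spec.groups:
        for k in range(group.n):
            seed = spec.base_seed + idx
            idx += 1
            params = _individual_params(group, seed, spec.param_cv)
            provenance["individuals"].append(
                {
                    "group": group.label,
                    "seed": seed,
                    "params": {k2: dataclasses.asdict(v) for k2, v in params.items()},
                }
            )
            try:
                row = _measure_individual(params)
            except ZfCardioError as exc:
                failures.append({"group": group.label, "seed": seed, "error": str(exc)})
                continue
            row["group"] = group.label
            row["seed"] = seed
            rows.append(row)

    table = pd.DataFrame(rows)
    for group in spec.groups:
        n_ok = int((table["group"] == group.label).sum()) if len(table) else 0
        if n_ok < 3:
            raise CohortError(
                f"group {group.label!r} has only {n_ok} measured individuals (< 3)"
            )

    g0, g1 = spec.groups[0].label, spec.groups[1].label
    metrics = [c for c in table.columns if c not in ("group", "seed")]
    comparisons = {}
    for m in metrics:
        a = table.loc[table["group"] == g0, m].dropna().to_numpy()
        b = table.loc[table["group"] == g1, m].dropna().to_numpy()
        if a.size >= 2 and b.size >= 2:
            comparisons[m] = compare_groups(a, b, policy="auto")
    return CohortResult(table=table, comparisons=comparisons, failures=failures, provenance=provenance)
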