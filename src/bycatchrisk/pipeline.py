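"""End-to-end orchestration: simulate -> harmonize -> recruit -> estimate.

The stages mirror the analysis flow: harmonize raw effort into per-bin
standard units; drift particle cohorts and scale them into abundance;
compute observed bycatch rates, summarize, and extrapolate.  Each stage is
a plain function over in-memory tables; the CLI adds file I/O around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import effort as effort_mod
from . import estimator, recruitment, synthetic
from .errors import DataError
from .grid import Membership
from .synthetic import SyntheticWorld

log = logging.getLogger("bycatchrisk")


@dataclass
class SimulationBundle:
    """Everything one synthetic run produces, with its ground truth."""

    world: SyntheticWorld
    velocity: xr.Dataset
    hatchlings: pd.DataFrame
    raw_effort: dict[str, pd.DataFrame]
    effort: pd.DataFrame  # harmonized per-bin
    fractions: pd.DataFrame  # recruitment field p(bin, region, age)
    components: pd.DataFrame  # abundance by age/region component
    abundance: pd.DataFrame  # aggregated T_p per (species, year, bin)
    bycatch: pd.DataFrame
    q_true: pd.DataFrame


@dataclass
class EstimationResult:
    """All estimator outputs for one input bundle."""

    rates: pd.DataFrame
    excluded: pd.DataFrame
    summaries: list[estimator.RateSummary]
    summary: pd.DataFrame
    risk: pd.DataFrame
    estimates: pd.DataFrame
    annual: pd.DataFrame
    percent: pd.DataFrame
    rate_trends: pd.DataFrame
    effort_trends: pd.DataFrame


def run_recruitment(
    world: SyntheticWorld,
    velocity: xr.Dataset,
    hatchlings: pd.DataFrame,
    step_hours: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drift every region's cohort and scale into abundance.

    The synthetic flow is stationary, so one drift per region serves every
    cohort year; returns (fractions, components, aggregated abundance).
    """
    rng = synthetic.component_rng(world.seed, "release")
    ages = np.asarray(world.age_classes, dtype=float)
    frac_parts = []
    for sched in world.schedules():
        traj = recruitment.drift_region(
            velocity, sched, ages_years=ages, step_hours=step_hours, rng=rng
        )
        if traj.n_particles != recruitment.count_particles_per_region_year(sched):
            raise DataError("particle budget not conserved")  # defensive
        frac_parts.append(
            recruitment.classify_coastal_recruits(
                traj, world.grid, set(world.coastal_bins), ages, region=sched.region
            )
        )
    fractions = pd.concat(frac_parts, ignore_index=True)
    comp_parts = []
    for sp in world.species:
        usable = [a for a in world.age_classes if a <= recruitment.SPECIES_AGE_CAP[sp]]
        comp_parts.append(
            recruitment.abundance(hatchlings, fractions, sp, world.years)
            if usable
            else pd.DataFrame()
        )
    components = pd.concat(comp_parts, ignore_index=True)
    abundance = recruitment.aggregate_abundance(components)
    return fractions, components, abundance


def simulate(world: SyntheticWorld, step_hours: float = 0.5) -> SimulationBundle:
    """Generate a complete, self-consistent synthetic input bundle."""
    velocity = synthetic.gen_velocity_field(world)
    hatchlings = synthetic.gen_hatchlings(world)
    raw = synthetic.gen_effort(world)
    harmonized = effort_mod.harmonize_effort(raw, world.membership)
    fractions, components, abundance = run_recruitment(
        world, velocity, hatchlings, step_hours=step_hours
    )
    bycatch = synthetic.gen_bycatch(world, abundance, harmonized)
    log.info(
        "simulated world: %d particles/region, %d bycatch records (%d nonzero)",
        world.particles_per_day * world.window_days,
        len(bycatch),
        int((bycatch["count"] > 0).sum()),
    )
    return SimulationBundle(
        world=world,
        velocity=velocity,
        hatchlings=hatchlings,
        raw_effort=raw,
        effort=harmonized,
        fractions=fractions,
        components=components,
        abundance=abundance,
        bycatch=bycatch,
        q_true=world.q_true_table(),
    )


def effort_trends(effort: pd.DataFrame) -> pd.DataFrame:
    """Pearson trend of total harmonized effort against year, per gear."""
    rows = []
    for gear, grp in effort.groupby("gear", sort=True):
        series = grp.groupby("year")["effort"].sum()
        res = estimator.trend_test(series)
        rows.append({"gear": gear, **res})
    return pd.DataFrame(rows)


def estimate(
    bycatch: pd.DataFrame,
    abundance: pd.DataFrame,
    effort: pd.DataFrame,
    membership: Membership | None = None,
) -> EstimationResult:
    """Full estimator sequence: rates -> summaries -> risk -> totals."""
    rates, excluded = estimator.compute_rates(bycatch, abundance, effort, membership)
    if excluded.shape[0]:
        log.warning(
            "%d bycatch records lacked matching abundance/effort and were excluded",
            excluded.shape[0],
        )
    summaries = estimator.summarize_rates(rates)
    risk = estimator.risk_indices(abundance, effort)
    estimates = estimator.extrapolate_bycatch(summaries, risk)
    annual = estimator.annual_summary(estimates)
    percent = estimator.percent_of_population(estimates, abundance)
    return EstimationResult(
        rates=rates,
        excluded=excluded,
        summaries=summaries,
        summary=estimator.summary_table(summaries),
        risk=risk,
        estimates=estimates,
        annual=annual,
        percent=percent,
        rate_trends=estimator.rate_trend_check(rates),
        effort_trends=effort_trends(effort),
    )


def run_demo(seed: int = 0, **world_kwargs) -> tuple[SimulationBundle, EstimationResult]:
    """Simulate the demo world and estimate back from its outputs."""
    world = synthetic.demo_world(seed=seed, **world_kwargs)
    bundle = simulate(world)
    result = estimate(
        bundle.bycatch, bundle.abundance, bundle.effort, world.membership
    )
    return bundle, result
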