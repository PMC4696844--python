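"""End-to-end two-deme validation study.

Runs the discrete subdivided chain for a panel of subdivided sample
configurations and compares the Monte-Carlo estimates against the exact
solver evaluated at the combined sample with the rescaled parameters
(theta * delta, rho * delta).  Two standard scenarios share the backward
migration matrix M = [[0.9, 0.1], [0.2, 0.8]] (stationary xi = (2/3, 1/3)):
the conservative one sets the deme fractions q' = xi (delta = 1), the
non-conservative one q' = (1/5, 4/5) (delta = 36/85).

Estimates come from independent replicate chains with the standard error
taken across replicates; statistics dominated by which gamete type is
currently fixed decorrelate only on the substitution timescale ~1/u0
generations, and independent replicates keep the error bars honest there.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .models import MigrationModel, SampleConfig, SubdividedSample, make_symmetric_diallelic
from .simulate import ChainSettings, deme_sizes, discrete_rates, estimate_replicated
from .solver import solve_probabilities
from .substructure import combine_samples, effective_params

__all__ = [
    "STUDY_ROWS",
    "TWO_DEME_M",
    "ScenarioSpec",
    "ComparisonReport",
    "two_deme_scenarios",
    "run_scenario",
    "reproduce_tables",
]

# Subdivided configurations of the validation panel, as per-deme row-major
# c-tuples (c_11, c_12, c_21, c_22); all gametes fully typed.
STUDY_ROWS: tuple[tuple[tuple[int, ...], ...], ...] = (
    ((0, 0, 1, 0), (0, 0, 0, 1)),
    ((0, 0, 1, 1), (0, 0, 1, 0)),
    ((1, 0, 2, 0), (1, 0, 2, 0)),
    ((4, 0, 0, 0), (2, 0, 0, 0)),
    ((3, 0, 0, 0), (2, 1, 0, 0)),
    ((1, 1, 0, 0), (0, 0, 0, 1)),
)

TWO_DEME_M: tuple[tuple[float, ...], ...] = ((0.9, 0.1), (0.2, 0.8))


@dataclass(frozen=True)
class ScenarioSpec:
    """A named subdivided-population scenario for the symmetric diallelic model.

    ``theta`` and ``rho`` are reference values calibrated at N_e = N; the
    chain runs with the implied fixed per-generation rates u0 = theta/(4N),
    r0 = rho/(4N), so substructure rescales the effective values to
    (theta * delta, rho * delta).  ``n_samples`` is the retained count per
    replicate chain.
    """

    label: str
    M: tuple
    q_prime: tuple
    N: int
    theta: float
    rho: float
    samples: tuple[SubdividedSample, ...]
    burn_in: int
    thin: int
    n_samples: int
    n_replicates: int
    seed: int


def two_deme_scenarios(N: int = 400, n_samples: int = 500, n_replicates: int = 8,
                       seed: int = 20240, theta: float = 0.01, rho: float = 50.0
                       ) -> tuple[ScenarioSpec, ScenarioSpec]:
    """The conservative (q' = xi) and non-conservative (q' = (1/5, 4/5)) scenarios."""
    samples = tuple(SubdividedSample.from_flat(rows) for rows in STUDY_ROWS)
    common = dict(M=TWO_DEME_M, N=N, theta=theta, rho=rho, samples=samples,
                  burn_in=10 * N, thin=max(N, 1000), n_samples=n_samples,
                  n_replicates=n_replicates)
    first = ScenarioSpec(label="conservative", q_prime=(2 / 3, 1 / 3), seed=seed, **common)
    second = ScenarioSpec(label="non-conservative", q_prime=(1 / 5, 4 / 5), seed=seed + 1,
                          **common)
    return first, second


@dataclass
class ComparisonReport:
    """Per-configuration chain-vs-solver comparison for one scenario.

    Rows whose monomial fired in too few retained states are below the
    resolution of the run; they are reported (with z = NaN when the SE is
    zero) but excluded from :meth:`resolved`, hence from the |z| <= 3 gate.
    """

    label: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    #: minimum non-zero monomial evaluations for the z test to be in its CLT regime
    min_events: int = 10

    @property
    def max_abs_z(self) -> float:
        return float(self.resolved()["z"].abs().max())

    def resolved(self) -> pd.DataFrame:
        """Rows where the z test is meaningful (enough events, positive SE)."""
        return self.table[(self.table["se"] > 0) & (self.table["events"] >= self.min_events)]

    def to_tsv(self, path) -> None:
        """Write the comparison as TSV with a JSON metadata sidecar."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")


def run_scenario(spec: ScenarioSpec, init="uniform", progress=None) -> ComparisonReport:
    """Run one scenario end to end.

    Computes xi, delta and the rescaled parameters, solves the recursion for
    every combined configuration, runs the replicate chains, and scores each
    panel row with z = (estimate - solver) / SE.
    """
    mig = MigrationModel(spec.M, spec.q_prime)
    theta_eff, rho_eff = effective_params(spec.theta, spec.rho, mig.delta)
    params = make_symmetric_diallelic(theta_eff, rho_eff)

    combined = [combine_samples(s) for s in spec.samples]
    n_max = max(c.n for c in combined)
    # the universe of the monomorphic size-n_max configuration contains every
    # full-gamete configuration of size <= n_max
    anchor = np.zeros((2, 2), dtype=int)
    anchor[0, 0] = n_max
    table = solve_probabilities(SampleConfig.full(anchor), params)

    u0, r0 = discrete_rates(spec.theta, spec.rho, spec.N)
    settings = ChainSettings(N=spec.N, N_alpha=deme_sizes(spec.N, spec.q_prime),
                             u0=u0, r0=r0, burn_in=spec.burn_in, thin=spec.thin,
                             seed=spec.seed)
    t0 = time.time()
    estimates = estimate_replicated(settings, params.mutation, np.asarray(spec.M),
                                    list(spec.samples), n_replicates=spec.n_replicates,
                                    samples_per_replicate=spec.n_samples, init=init)
    elapsed = time.time() - t0
    generations = spec.n_replicates * (spec.burn_in + spec.n_samples * spec.thin)
    if progress is not None:
        progress(f"{spec.label}: {spec.n_replicates} replicate chains, "
                 f"{generations} generations total, {elapsed:.1f}s")

    rows = []
    for sub, comb, (est, se, events) in zip(spec.samples, combined, estimates):
        exact = table.q(comb)
        rows.append({
            "subdivided": " + ".join(str(s.flat()) for s in sub),
            "combined": str(comb.flat()),
            "estimate": est,
            "se": se,
            "events": events,
            "solver": exact,
            "z": (est - exact) / se if se > 0 else np.nan,
        })
    frame = pd.DataFrame(rows)
    metadata = {
        "label": spec.label,
        "xi": list(mig.xi),
        "delta": mig.delta,
        "theta_eff": theta_eff,
        "rho_eff": rho_eff,
        "N": spec.N,
        "N_alpha": list(settings.N_alpha),
        "u0": u0,
        "r0": r0,
        "burn_in": spec.burn_in,
        "thin": spec.thin,
        "n_samples_per_replicate": spec.n_samples,
        "n_replicates": spec.n_replicates,
        "seed": spec.seed,
        "init": init if isinstance(init, str) else "array",
        "solver_residual": table.residual,
        "chain_seconds": elapsed,
    }
    return ComparisonReport(label=spec.label, table=frame, metadata=metadata)


def reproduce_tables(scale: str = "desk", seed: int = 20240, out_dir=None,
                     progress=None) -> tuple[ComparisonReport, ComparisonReport]:
    """Run both two-deme scenarios and return their comparison reports.

    ``scale="desk"`` uses N = 400 with 8 replicate chains of 5 * 10^5
    post-burn-in generations each per scenario; ``scale="full"`` documents
    the full-size study (N = 10,000, 10^12 generations, thinning 10^5) and
    is far beyond an interactive run.  At desk scale every resolved row
    (see :meth:`ComparisonReport.resolved`) must satisfy |z| <= 3; a
    :class:`ValidationError` listing the failing rows is raised otherwise.
    """
    if scale == "desk":
        spec1, spec2 = two_deme_scenarios(N=400, n_samples=500, n_replicates=8, seed=seed)
    elif scale == "full":
        spec1, spec2 = two_deme_scenarios(N=10_000, n_samples=10_000_000,
                                          n_replicates=2, seed=seed)
        spec1 = ScenarioSpec(**{**spec1.__dict__, "thin": 100_000})
        spec2 = ScenarioSpec(**{**spec2.__dict__, "thin": 100_000})
    else:
        raise ValidationError(f"unknown scale {scale!r}; use 'desk' or 'full'")
    reports = tuple(run_scenario(spec, progress=progress) for spec in (spec1, spec2))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(reports, start=1):
            rep.to_tsv(out_dir / f"comparison_scenario{i}.tsv")
    failures = []
    for rep in reports:
        resolved = rep.resolved()
        if resolved.empty:
            raise ValidationError(f"scenario {rep.label!r}: no retained samples hit "
                                  "any panel configuration")
        bad = resolved[resolved["z"].abs() > 3.0]
        for _, row in bad.iterrows():
            failures.append(f"{rep.label} {row['combined']}: z = {row['z']:.2f}")
    if failures:
        raise ValidationError("rows outside 3 SE: " + "; ".join(failures))
    return reports
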