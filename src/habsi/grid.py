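"""Factorial experiment harness and HAB vs NO-HAB aggregation.

The full design crosses ranking type (R), network (N), propagation
probability (PP), seed fraction (SP), habituation on/off (H), and the
kinetic constants alpha (A) and tau (T).  Alpha and tau are enumerated even
for habituation-off cells, matching the study's combination count: the
default factors give 2*4*2*2*2*2*5 = 640 combinations, 6400 runs at 10
replicates.  Each run gets its own seed derived from the base seed, the
combination index and the replicate index, so results are independent of
execution order and partially completed grids can be resumed.

Aggregation mirrors the study's summary tables: mean coverage after 5/10/15
steps and mean duration to 40%/80% coverage, grouped per parameter value,
with the habituated arm compared against the habituation-free arm by a
two-sided Mann-Whitney rank-sum test.  When grouping by alpha or tau the
NO-HAB baseline is the pool of all habituation-off runs (those factors do not
affect habituation-off dynamics, so the baseline row repeats).  The headline
effect sizes are the relative coverage decrease ``100*(noHab - hab)/noHab``
and the relative duration increase ``100*(hab - noHab)/noHab``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .fixtures import make_stand_in_networks
from .habituation import HabituationParams
from .network import read_edge_list, read_graphml
from .simulate import MAX_STEPS, SimulationConfig, run
from .util import derive_seed

__all__ = [
    "HAB_EXISTS",
    "HAB_NOT_EXISTS",
    "FACTOR_ORDER",
    "GridSpec",
    "GridPoint",
    "expand_grid",
    "run_seed",
    "point_config",
    "resolve_networks",
    "run_grid",
    "relative_coverage_decrease",
    "relative_duration_increase",
    "compare_distributions",
    "aggregate",
    "write_tables",
    "RUN_COLUMNS",
]

logger = logging.getLogger(__name__)

HAB_EXISTS = "exists"
HAB_NOT_EXISTS = "not_exists"

#: Cartesian-product order defining the combination index.
FACTOR_ORDER = ("ranking", "network", "pp", "sp", "habituation", "alpha", "tau")


@dataclass(frozen=True)
class GridSpec:
    """The factorial design.  Defaults reproduce the study's factor levels."""

    rankings: tuple = ("random", "degree")
    networks: tuple = ("standin:1", "standin:2", "standin:3", "standin:4")
    pps: tuple = (0.05, 0.1)
    sps: tuple = (0.01, 0.05)
    habituation: tuple = (HAB_EXISTS, HAB_NOT_EXISTS)
    alphas: tuple = (1.05, 1.2)
    taus: tuple = (5, 10, 15, 20, 25)
    replicates: int = 10
    base_rng_seed: int = 0
    coverage_target: float = 0.80
    max_steps: int = 1000
    record_steps: tuple = (5, 10, 15)
    thresholds: tuple = (0.4, 0.8)

    def __post_init__(self) -> None:
        for name in ("rankings", "networks", "pps", "sps", "habituation", "alphas", "taus"):
            if not getattr(self, name):
                raise ValueError(f"factor {name!r} must be non-empty")
        for h in self.habituation:
            if h not in (HAB_EXISTS, HAB_NOT_EXISTS):
                raise ValueError(f"habituation level must be {HAB_EXISTS!r} or {HAB_NOT_EXISTS!r}, got {h!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_combinations(self) -> int:
        return (
            len(self.rankings) * len(self.networks) * len(self.pps) * len(self.sps)
            * len(self.habituation) * len(self.alphas) * len(self.taus)
        )

    @property
    def n_runs(self) -> int:
        return self.n_combinations * self.replicates


@dataclass(frozen=True)
class GridPoint:
    """One combination of factor levels, with its index in expansion order."""

    index: int
    ranking: str
    network: str
    pp: float
    sp: float
    habituation: str
    alpha: float
    tau: float


def expand_grid(spec: GridSpec) -> list[GridPoint]:
    """Cartesian product of the factors in :data:`FACTOR_ORDER` order."""
    product = itertools.product(
        spec.rankings, spec.networks, spec.pps, spec.sps,
        spec.habituation, spec.alphas, spec.taus,
    )
    return [GridPoint(i, *combo) for i, combo in enumerate(product)]


def run_seed(base_rng_seed: int, combination_index: int, replicate: int) -> int:
    """Per-run RNG seed: stable hash of (base seed, combination, replicate)."""
    return derive_seed("run", base_rng_seed, combination_index, replicate)


def point_config(spec: GridSpec, point: GridPoint, replicate: int) -> SimulationConfig:
    """Simulation config for one grid point and replicate."""
    return SimulationConfig(
        pp=point.pp,
        seed_fraction=point.sp,
        ranking=point.ranking,
        habituation_enabled=point.habituation == HAB_EXISTS,
        hab_params=HabituationParams(alpha=point.alpha, tau=point.tau),
        coverage_target=spec.coverage_target,
        max_steps=spec.max_steps,
        rng_seed=run_seed(spec.base_rng_seed, point.index, replicate),
    )


def resolve_networks(spec: GridSpec, graphs: dict | None = None) -> dict:
    """Map each network label of the spec to a loaded graph.

    Labels resolve, in order: an entry in the user-supplied ``graphs``
    mapping; ``standin:i`` (the bundled synthetic stand-ins, built with a seed
    derived from the spec's base seed); a GraphML or edge-list file path.
    """
    resolved: dict = {}
    stand_ins = None
    for label in spec.networks:
        if graphs and label in graphs:
            resolved[label] = graphs[label]
        elif label.startswith("standin:"):
            if stand_ins is None:
                stand_ins = make_stand_in_networks(derive_seed("networks", spec.base_rng_seed))
            resolved[label] = stand_ins[int(label.split(":", 1)[1]) - 1]
        else:
            path = Path(label)
            resolved[label] = read_graphml(path) if path.suffix == ".graphml" else read_edge_list(path)
    return resolved


RUN_COLUMNS = [
    "combination", "replicate", "ranking", "network", "pp", "sp",
    "habituation", "alpha", "tau", "rng_seed",
    "coverage_step5", "coverage_step10", "coverage_step15",
    "duration_40", "duration_80", "final_coverage", "n_steps", "stop_reason",
]


def run_grid(
    spec: GridSpec,
    graphs: dict | None = None,
    out_csv: str | Path | None = None,
    resume: bool = True,
) -> pd.DataFrame:
    """Execute every combination x replicate and collect run records.

    Records are flushed to ``out_csv`` after every run when given; an existing
    file is used to skip already-completed (combination, replicate) pairs
    unless ``resume`` is False.  Per-run failures are logged and recorded with
    missing metrics rather than aborting the grid.
    """
    networks = resolve_networks(spec, graphs)
    done: set = set()
    records: list[dict] = []
    out_path = Path(out_csv) if out_csv is not None else None
    if out_path is not None and out_path.exists() and resume:
        prior = pd.read_csv(out_path)
        records = prior.to_dict("records")
        done = {(int(r["combination"]), int(r["replicate"])) for r in records}
    elif out_path is not None and out_path.exists():
        out_path.unlink()

    fh = None
    if out_path is not None:
        fresh = not out_path.exists()
        fh = out_path.open("a")
        if fresh:
            fh.write(",".join(RUN_COLUMNS) + "\n")

    try:
        for point in expand_grid(spec):
            g = networks[point.network]
            for rep in range(spec.replicates):
                if (point.index, rep) in done:
                    continue
                cfg = point_config(spec, point, rep)
                rec = {
                    "combination": point.index,
                    "replicate": rep,
                    "ranking": point.ranking,
                    "network": point.network,
                    "pp": point.pp,
                    "sp": point.sp,
                    "habituation": point.habituation,
                    "alpha": point.alpha,
                    "tau": point.tau,
                    "rng_seed": cfg.rng_seed,
                }
                try:
                    traj = run(g, cfg)
                except Exception:  # pragma: no cover - defensive
                    logger.exception("run failed at combination %d replicate %d", point.index, rep)
                    rec.update({k: None for k in RUN_COLUMNS[10:]})
                else:
                    d40 = traj.duration_to(spec.thresholds[0])
                    d80 = traj.duration_to(spec.thresholds[1])
                    rec.update(
                        {
                            "coverage_step5": traj.coverage_at(spec.record_steps[0]),
                            "coverage_step10": traj.coverage_at(spec.record_steps[1]),
                            "coverage_step15": traj.coverage_at(spec.record_steps[2]),
                            "duration_40": d40,
                            "duration_80": d80,
                            "final_coverage": traj.coverage_by_step[-1],
                            "n_steps": traj.n_steps,
                            "stop_reason": traj.stop_reason,
                        }
                    )
                records.append(rec)
                if fh is not None:
                    fh.write(",".join("" if rec[k] is None else str(rec[k]) for k in RUN_COLUMNS) + "\n")
                    fh.flush()
    finally:
        if fh is not None:
            fh.close()

    df = pd.DataFrame(records, columns=RUN_COLUMNS)
    # normalise numerics (missing durations -> NaN) so CSV round-trips compare equal
    text_cols = {"ranking", "network", "habituation", "stop_reason"}
    num_cols = [c for c in RUN_COLUMNS if c not in text_cols]
    df[num_cols] = df[num_cols].apply(pd.to_numeric, errors="coerce")
    return df.sort_values(["combination", "replicate"]).reset_index(drop=True)


def relative_coverage_decrease(mean_hab: float, mean_nohab: float) -> float:
    """Percent coverage lost to habituation: 100*(noHab - hab)/noHab."""
    if mean_nohab == 0:
        raise ZeroDivisionError("habituation-free mean coverage is zero")
    return 100.0 * (mean_nohab - mean_hab) / mean_nohab


def relative_duration_increase(mean_hab: float, mean_nohab: float) -> float:
    """Percent extra time under habituation: 100*(hab - noHab)/noHab."""
    if mean_nohab == 0:
        raise ZeroDivisionError("habituation-free mean duration is zero")
    return 100.0 * (mean_hab - mean_nohab) / mean_nohab


def compare_distributions(hab_values, nohab_values) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of the two arms.

    Returns (U statistic, p-value).  The runs are unpaired samples, hence the
    rank-sum rather than a paired signed-rank test.  If every pooled value is
    identical the test is degenerate: p = 1 with a warning.
    """
    hab = list(hab_values)
    nohab = list(nohab_values)
    if not hab or not nohab:
        raise ValueError("both samples must be non-empty")
    pooled = hab + nohab
    if all(v == pooled[0] for v in pooled):
        warnings.warn("all pooled values identical; rank-sum test degenerate, p=1", stacklevel=2)
        return len(hab) * len(nohab) / 2.0, 1.0
    res = stats.mannwhitneyu(hab, nohab, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


_GROUPINGS = (
    ("NET", "network", False),
    ("ALPHA", "alpha", True),
    ("PP", "pp", False),
    ("SP", "sp", False),
    ("TAU", "tau", True),
)


def _grouping_rows(runs: pd.DataFrame):
    """Yield (parameter, value, hab subset, nohab subset) per summary row.

    The first row pools everything.  For alpha/tau groupings the NO-HAB arm is
    pooled across all habituation-off runs (those factors are inert there).
    """
    hab = runs[runs["habituation"] == HAB_EXISTS]
    nohab = runs[runs["habituation"] == HAB_NOT_EXISTS]
    yield "ALL", "", hab, nohab
    for param, col, pool_nohab in _GROUPINGS:
        for value in sorted(runs[col].unique()):
            h = hab[hab[col] == value]
            nh = nohab if pool_nohab else nohab[nohab[col] == value]
            yield param, value, h, nh


def aggregate(runs: pd.DataFrame) -> dict:
    """Build the four summary tables from run records.

    Returns ``{"coverage", "duration", "decrease", "increase"}`` DataFrames:
    mean coverage (percent) after 5/10/15 steps and mean duration (steps) to
    40%/80% coverage, per arm, with rank-sum p-values; plus the derived
    relative-change tables.  Runs whose duration is missing (step cap hit
    before the threshold) are excluded from duration means, with the excluded
    count reported per cell.
    """
    cov_rows, dur_rows, dec_rows, inc_rows = [], [], [], []
    cov_cols = [("coverage_step5", "5"), ("coverage_step10", "10"), ("coverage_step15", "15")]
    dur_cols = [("duration_40", "40"), ("duration_80", "80")]

    for param, value, h, nh in _grouping_rows(runs):
        if h.empty or nh.empty:
            continue
        cov = {"parameter": param, "value": value}
        dec = {"parameter": param, "value": value}
        for col, label in cov_cols:
            mean_h = 100.0 * h[col].mean()
            mean_nh = 100.0 * nh[col].mean()
            _, p = compare_distributions(h[col], nh[col])
            cov[f"hab_{label}"] = mean_h
            cov[f"p_{label}"] = p
            cov[f"nohab_{label}"] = mean_nh
            dec[f"decrease_{label}"] = relative_coverage_decrease(mean_h, mean_nh)
            dec[f"p_{label}"] = p
        cov_rows.append(cov)
        dec_rows.append(dec)

        dur = {"parameter": param, "value": value}
        inc = {"parameter": param, "value": value}
        for col, label in dur_cols:
            vals_h = h[col].dropna()
            vals_nh = nh[col].dropna()
            n_missing = int(h[col].isna().sum() + nh[col].isna().sum())
            if n_missing:
                logger.info(
                    "%s=%s duration-to-%s%%: excluded %d run(s) that hit the step cap",
                    param, value, label, n_missing,
                )
            if vals_h.empty or vals_nh.empty:
                dur[f"hab_{label}"] = dur[f"p_{label}"] = dur[f"nohab_{label}"] = None
                inc[f"increase_{label}"] = inc[f"p_{label}"] = None
                dur[f"excluded_{label}"] = n_missing
                continue
            mean_h = vals_h.mean()
            mean_nh = vals_nh.mean()
            _, p = compare_distributions(vals_h, vals_nh)
            dur[f"hab_{label}"] = mean_h
            dur[f"p_{label}"] = p
            dur[f"nohab_{label}"] = mean_nh
            dur[f"excluded_{label}"] = n_missing
            inc[f"increase_{label}"] = relative_duration_increase(mean_h, mean_nh)
            inc[f"p_{label}"] = p
        dur_rows.append(dur)
        inc_rows.append(inc)

    return {
        "coverage": pd.DataFrame(cov_rows),
        "duration": pd.DataFrame(dur_rows),
        "decrease": pd.DataFrame(dec_rows),
        "increase": pd.DataFrame(inc_rows),
    }


def write_tables(tables: dict, outdir: str | Path) -> dict:
    """Write the four aggregate tables as CSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {
        "coverage": "tables_coverage.csv",
        "duration": "tables_duration.csv",
        "decrease": "tables_decrease.csv",
        "increase": "tables_increase.csv",
    }
    paths = {}
    for key, fname in names.items():
        path = outdir / fname
        tables[key].to_csv(path, index=False)
        paths[key] = path
    return paths
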