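"""Benchmark metrics, Mendelian-error QC and GE-rate calibration.

Detected recombination events are scored against simulated truth with
precision, recall, F1 and resolution; Mendelian-error (ME) rates are the
observable proxy for the underlying genotyping-error (GE) rate, related
through a linear calibration curve fitted on simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from statistics import median

import numpy as np
import pandas as pd

from .constants import ALLELE_MISSING
from .events import RecombinationEvent
from .plink_io import GenotypeTable, MarkerMap, Pedigree
from .simulator import SimConfig, SimulationTruth, simulate_population

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class PerformanceReport:
    """Event-detection scores for one run against simulated truth."""

    precision: float
    recall: float
    f1: float
    resolution: float | None
    adjusted_resolution: float | None
    n_detected: int
    n_true: int
    n_matched: int
    pct_filtered: float | None = None
    degenerate: bool = False  # a zero denominator forced a metric to 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def match_events(
    detected: list[RecombinationEvent],
    truth: SimulationTruth,
    meioses: list[tuple[str, str]] | None = None,
) -> tuple[int, list[list[int]]]:
    """Match detected intervals to true breakpoints on the same meiosis.

    A detected event matches every true breakpoint b with
    start_bp <= b <= end_bp; an event containing several breakpoints
    still counts once toward n_matched, while every unmatched breakpoint
    stays in the recall denominator. Returns (n_matched, per-event lists
    of matched breakpoints, aligned with ``detected``).
    """
    if meioses is None:
        meioses = list(truth.breakpoints)
    meiosis_set = set(meioses)
    for ev in detected:
        if ev.meiosis not in meiosis_set:
            raise EvaluationError(
                f"detected event on unknown meiosis {ev.meiosis}"
            )
    matches: list[list[int]] = []
    n_matched = 0
    for ev in detected:
        bps = truth.breakpoints.get(ev.meiosis, [])
        hit = [b for b in bps if ev.start_bp <= b <= ev.end_bp]
        matches.append(hit)
        if hit:
            n_matched += 1
    return n_matched, matches


def precision_recall_f1(
    n_matched: int, n_detected: int, n_true: int
) -> tuple[float, float, float]:
    """precision = matched/detected, recall = matched/true, F1 harmonic mean.

    Zero denominators yield 0 for the affected metric.
    """
    if n_matched > n_detected or n_matched > n_true:
        raise EvaluationError(
            f"n_matched={n_matched} exceeds n_detected={n_detected} or n_true={n_true}"
        )
    precision = n_matched / n_detected if n_detected else 0.0
    recall = n_matched / n_true if n_true else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def adjusted_resolution(
    precision: float, detected: list[RecombinationEvent]
) -> tuple[float | None, float | None]:
    """Resolution = 1/median(candidate SNP intervals per recombination interval).

    Adjusted resolution multiplies by precision: the probability that a
    given SNP interval inside a detected interval is the true locus of a
    true event. Undefined (None) when there are no events.
    """
    if not detected:
        return None, None
    med = median(ev.n_intervals for ev in detected)
    resolution = 1.0 / med
    return resolution, precision * resolution


def pct_filtered(raw_events, filtered_events) -> float | None:
    """Percentage of raw (min=1, imputeNot) events removed by filtering."""
    n_raw = raw_events if isinstance(raw_events, int) else len(raw_events)
    n_f = filtered_events if isinstance(filtered_events, int) else len(filtered_events)
    if n_raw == 0:
        return None
    return 100.0 * (n_raw - n_f) / n_raw


def evaluate_detection(
    detected: list[RecombinationEvent],
    truth: SimulationTruth,
    meioses: list[tuple[str, str]] | None = None,
    raw_events=None,
) -> PerformanceReport:
    """Full scoring of one detector run against truth."""
    n_matched, _ = match_events(detected, truth, meioses)
    if meioses is None:
        meioses = list(truth.breakpoints)
    n_true = sum(len(truth.breakpoints.get(m, [])) for m in meioses)
    n_detected = len(detected)
    precision, recall, f1 = precision_recall_f1(n_matched, n_detected, n_true)
    resolution, adjusted = adjusted_resolution(precision, detected)
    return PerformanceReport(
        precision=precision,
        recall=recall,
        f1=f1,
        resolution=resolution,
        adjusted_resolution=adjusted,
        n_detected=n_detected,
        n_true=n_true,
        n_matched=n_matched,
        pct_filtered=(
            pct_filtered(raw_events, detected) if raw_events is not None else None
        ),
        degenerate=(n_detected == 0 or n_true == 0),
    )


# ---------------------------------------------------------------------------
# Mendelian-error QC
# ---------------------------------------------------------------------------

def _trio_violations(
    fa: np.ndarray, mo: np.ndarray, of: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(tested, violated) masks per locus for one trio."""
    tested = (
        (fa != ALLELE_MISSING).all(axis=1)
        & (mo != ALLELE_MISSING).all(axis=1)
        & (of != ALLELE_MISSING).all(axis=1)
    )
    carries = lambda g, a: (g[:, 0] == a) | (g[:, 1] == a)
    o1, o2 = of[:, 0], of[:, 1]
    hom_ok = carries(fa, o1) & carries(mo, o1)
    het_ok = (carries(fa, o1) & carries(mo, o2)) | (carries(fa, o2) & carries(mo, o1))
    consistent = np.where(o1 == o2, hom_ok, het_ok)
    return tested, tested & ~consistent


def me_rate(
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    scope: str = "global",
):
    """Mendelian-error rate over trio-locus comparisons.

    scope="global" returns one rate; "per-generation" a dict keyed by
    offspring generation; "per-marker" an array over loci. Trios require
    both parents genotyped; loci with any missing member are not tested.
    Returns NaN (or empty containers) when nothing is testable.
    """
    if scope not in ("global", "per-generation", "per-marker"):
        raise EvaluationError(f"unknown scope {scope!r}")
    n_loci = genotypes.n_loci
    tested_marker = np.zeros(n_loci, dtype=np.int64)
    viol_marker = np.zeros(n_loci, dtype=np.int64)
    per_gen: dict[int, list[int]] = {}
    for rec in pedigree.records:
        if rec.father is None or rec.mother is None:
            continue
        if not all(x in genotypes for x in (rec.iid, rec.father, rec.mother)):
            continue
        tested, violated = _trio_violations(
            genotypes.genotype(rec.father),
            genotypes.genotype(rec.mother),
            genotypes.genotype(rec.iid),
        )
        tested_marker += tested
        viol_marker += violated
        g = pedigree.generation[rec.iid]
        acc = per_gen.setdefault(g, [0, 0])
        acc[0] += int(tested.sum())
        acc[1] += int(violated.sum())
    if scope == "per-marker":
        with np.errstate(invalid="ignore"):
            return np.where(
                tested_marker > 0, viol_marker / np.maximum(tested_marker, 1), np.nan
            )
    if scope == "per-generation":
        return {
            g: (v / t if t else float("nan")) for g, (t, v) in sorted(per_gen.items())
        }
    total_t = int(tested_marker.sum())
    return float(viol_marker.sum()) / total_t if total_t else float("nan")


def filter_markers_by_me(
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    marker_map: MarkerMap | None = None,
    threshold: float = 0.10,
) -> tuple[GenotypeTable, MarkerMap | None]:
    """Drop markers whose per-marker ME rate strictly exceeds the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise EvaluationError("threshold must be in (0, 1]")
    rates = me_rate(genotypes, pedigree, scope="per-marker")
    keep = ~(rates > threshold)  # NaN (untested) markers are kept
    if not keep.any():
        raise EvaluationError("ME filter would drop every marker")
    dropped = int((~keep).sum())
    if dropped:
        log.info("ME filter dropped %d markers (> %.0f%% ME)", dropped, 100 * threshold)
    return (
        genotypes.subset_loci(keep),
        marker_map.subset(keep) if marker_map is not None else None,
    )


# ---------------------------------------------------------------------------
# GE-from-ME calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Least-squares linear fit of measured ME rate against simulated GE rate."""

    slope: float
    intercept: float
    ge_grid: list[float]
    me_values: list[float]

    def predict(self, ge: float) -> float:
        return self.slope * ge + self.intercept

    def invert(self, me: float) -> float:
        return (me - self.intercept) / self.slope


def calibrate_ge_from_me(
    sim_config_template: SimConfig,
    ge_grid: list[float],
    n_reps: int = 1,
    seed: int = 0,
    error_generations: tuple[int, ...] | None = None,
) -> CalibrationCurve:
    """Fit the GE->ME reference curve on simulated populations.

    Each grid GE rate is applied to generations G2..depth (the error-
    bearing generations), the population simulated n_reps times and the
    global ME rate measured; the curve is the least-squares line
    ME = slope*GE + intercept with an ``invert`` method mapping an
    observed ME rate back to a GE rate.
    """
    if len(ge_grid) < 3:
        raise EvaluationError("ge_grid needs at least 3 rates")
    if len(set(ge_grid)) < 2:
        raise EvaluationError("ge_grid is degenerate (no variance)")
    if n_reps < 1:
        raise EvaluationError("n_reps must be >= 1")
    if error_generations is None:
        error_generations = tuple(
            g for g in range(2, sim_config_template.depth + 1)
        )
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(ge_grid) * n_reps) >> 1]
    me_values = []
    k = 0
    for ge in ge_grid:
        rates = []
        for _ in range(n_reps):
            cfg = replace(
                sim_config_template,
                ge_rates={g: float(ge) for g in error_generations},
                seed=child_seeds[k],
            )
            k += 1
            pop = simulate_population(cfg)
            rates.append(me_rate(pop.genotypes, pop.pedigree, scope="global"))
        me_values.append(float(np.mean(rates)))
    slope, intercept = np.polyfit(np.asarray(ge_grid, float), np.asarray(me_values), 1)
    if slope == 0:
        raise EvaluationError("degenerate calibration fit (zero slope)")
    return CalibrationCurve(float(slope), float(intercept), list(ge_grid), me_values)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep_performance(
    template: SimConfig,
    ge_rates: list[float],
    min_values: list,
    settings: list[tuple[str, str]] = (("imputeNot", "correctNot"),),
    n_reps: int = 3,
    seed: int = 0,
    thr: int = 0,
) -> pd.DataFrame:
    """Benchmark grid: GE rate x min threshold x (imp, cor) setting.

    Simulates ``n_reps`` populations per GE rate (paired across settings),
    runs the pipeline at every combination and scores it against truth.
    Returns one row per (ge, min, imp, cor, replicate) with the usual
    metrics plus the percentage of events removed relative to the raw
    (min=1, imputeNot) run on the same population.
    """
    from .origins import FilterConfig
    from .pipeline import run_pipeline

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(len(ge_rates) * n_reps) >> 1]
    rows = []
    k = 0
    for ge in ge_rates:
        for rep in range(n_reps):
            rates = {g: float(ge) for g in range(2, template.depth + 1)} if ge else {}
            pop = simulate_population(
                replace(template, ge_rates=rates, seed=rep_seeds[k])
            )
            k += 1
            raw = run_pipeline(
                pop.pedigree, pop.genotypes, pop.marker_map, FilterConfig(min=1)
            )
            for imp, cor in settings:
                for mn in min_values:
                    cfg = FilterConfig(min=mn, imp=imp, cor=cor, thr=thr)
                    res = run_pipeline(
                        pop.pedigree, pop.genotypes, pop.marker_map, cfg
                    )
                    rep_score = evaluate_detection(
                        res.events, pop.truth, raw_events=raw.events
                    )
                    rows.append(
                        {
                            "ge_rate": ge,
                            "min": str(mn),
                            "imp": imp,
                            "cor": cor,
                            "replicate": rep,
                            **rep_score.as_dict(),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recombination-count maps
# ---------------------------------------------------------------------------

def co_count_map(
    events: list[RecombinationEvent], marker_map: MarkerMap
) -> pd.DataFrame:
    """Gap-normalized per-SNP-interval crossover counts.

    Each event distributes weight 1 evenly over the SNP intervals it
    spans, so the weight in each recombination gap sums to 1 and the
    total over the map equals the event count exactly.
    """
    n_intervals = marker_map.n_loci - 1
    weights = np.zeros(max(n_intervals, 0), dtype=float)
    for ev in events:
        span = ev.end_idx - ev.start_idx
        weights[ev.start_idx: ev.end_idx] += 1.0 / span
    markers = marker_map.markers
    chroms = marker_map.chromosomes
    rows = {
        "chrom": chroms[:-1] if n_intervals > 0 else [],
        "left_marker": markers[:-1],
        "right_marker": markers[1:],
        "weight": weights,
    }
    return pd.DataFrame(rows)
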