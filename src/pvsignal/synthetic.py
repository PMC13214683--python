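"""Synthetic JADER-schema databases with known ground truth.

Every pipeline stage is testable without the real (licensed /
non-redistributable) extract: the generator emits the exact four-table
CSV schema consumed by :mod:`pvsignal.srs_store`, plus a ground-truth
record of the planted structure.

Statistical structure
---------------------
Reports are independent. Each drug enters a report as a Bernoulli draw on
its marginal probability, with a role (suspected / concomitant /
interacting) and route drawn from per-drug categorical distributions.
Each preferred term occurs with probability ``baseline × prod(lambda)``
over the *present* drugs that carry a planted rate multiplier for that
term (capped at 1). Event onsets follow a planted per-pair Weibull when
one applies, else a background Weibull; the continuous draw is rounded up
to a whole day so the day-1 convention of the extractor is reproduced
exactly. Treatment duration is geometric, so the post-cessation window
rule is exercised. A configurable fraction of dates is blanked or
truncated to year-month, and a configurable fraction of cases receives an
extra (identical) higher version to exercise deduplication.

Deliberately *not* modelled: polypharmacy confounding, reporting-rate
time trends (Weber effect), and real JADER marginal frequencies.

Randomness comes from a single seed; independent child streams are
spawned in a fixed, documented order (demographics, drugs, events,
onsets, missingness, duplicates) so extending one table never perturbs
the draws of another.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DrugSpec:
    name: str
    marginal: float
    role_probs: dict[str, float] = field(default_factory=lambda: {
        "suspected": 0.7, "concomitant": 0.25, "interacting": 0.05})
    route_probs: dict[str, float] = field(default_factory=lambda: {
        "intravenous": 0.6, "oral": 0.2, "other": 0.05, "unspecified": 0.15})


@dataclass
class TermSpec:
    pt_code: str
    baseline: float


@dataclass
class SyntheticConfig:
    """Full description of a synthetic SRS database.

    ``signals`` maps ``(drug, pt_code)`` to a rate multiplier lambda >= 0;
    ``onset`` maps ``(drug, pt_code)`` to a planted Weibull ``(alpha,
    beta)`` in days. ``seed`` is mandatory — identical config + seed gives
    byte-identical output files.
    """

    n_reports: int
    drugs: list[DrugSpec]
    terms: list[TermSpec]
    seed: int
    signals: dict[tuple[str, str], float] = field(default_factory=dict)
    onset: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    background_onset: tuple[float, float] = (8.0, 1.0)
    date_missing_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    sex_probs: dict[str, float] = field(default_factory=lambda: {
        "male": 0.62, "female": 0.35, "unspecified": 0.03})
    age_probs: dict[str, float] = field(default_factory=lambda: {
        "<20": 0.05, "20-59": 0.24, ">=60": 0.67, "unspecified": 0.04})
    weight_probs: dict[str, float] = field(default_factory=lambda: {
        "<40": 0.08, "40-69": 0.44, ">=70": 0.09, "unspecified": 0.39})
    start_window_days: int = 3650          # start dates uniform over this window
    mean_duration_days: float = 14.0       # geometric treatment duration
    start_epoch: str = "2015-01-01"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for spec in self.drugs:
            if not 0 <= spec.marginal <= 1:
                raise ValueError(f"marginal out of [0,1] for drug {spec.name}")
            for dist in (spec.role_probs, spec.route_probs):
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for drug {spec.name} "
                                     "do not sum to 1")
        baselines = {t.pt_code: t.baseline for t in self.terms}
        for t in self.terms:
            if not 0 <= t.baseline <= 1:
                raise ValueError(f"baseline out of [0,1] for term {t.pt_code}")
        for (drug, term), lam in self.signals.items():
            if lam < 0:
                raise ValueError(f"negative multiplier for ({drug}, {term})")
            if term in baselines and baselines[term] * lam > 1:
                raise ValueError(
                    f"infeasible probability for pair ({drug}, {term}): "
                    f"baseline {baselines[term]} x lambda {lam} > 1")
        for (drug, term), (a, b) in self.onset.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"onset parameters must be positive for "
                                 f"({drug}, {term})")


@dataclass
class GroundTruth:
    """Planted structure: per-pair cell probabilities, PRR and Weibull."""

    pairs: dict[tuple[str, str], dict]

    def to_json(self) -> str:
        return json.dumps(
            {f"{d}|{t}": v for (d, t), v in sorted(self.pairs.items())},
            indent=1, sort_keys=True)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["demo", "drug", "event", "onset", "missing", "duplicate"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _categorical(rng, probs: dict[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    return np.array(keys)[rng.choice(len(keys), size=size, p=list(probs.values()))]


def expected_prr(config: SyntheticConfig, drug: str, term: str,
                 allowed_routes: frozenset | None = None) -> float:
    """Closed-form expected PRR for a planted pair under the generator.

    Exposure means the drug is present with role ``suspected`` and an
    allowed route (all routes by default). The event probability given a
    drug-presence configuration is ``min(1, baseline × prod lambda)``;
    the expectation enumerates the joint presence of every drug carrying
    a multiplier for the term, exploiting independence across drugs.
    """
    spec = next((s for s in config.drugs if s.name == drug), None)
    tspec = next((t for t in config.terms if t.pt_code == term), None)
    if spec is None or tspec is None:
        raise KeyError(f"unknown pair ({drug}, {term})")
    route_ok = 1.0 if allowed_routes is None else sum(
        p for r, p in spec.route_probs.items()
        if r in allowed_routes or r == "unspecified")
    m = spec.marginal
    e = m * spec.role_probs.get("suspected", 0.0) * route_ok
    p_present, p_absent = _event_probs(config, drug, term)
    if e >= 1.0:
        return math.nan
    p_unexposed = ((1 - m) * p_absent + (m - e) * p_present) / (1 - e)
    if p_unexposed == 0:
        return math.inf if p_present > 0 else math.nan
    return p_present / p_unexposed


def _event_probs(config: SyntheticConfig, drug: str,
                 term: str) -> tuple[float, float]:
    """P(event | target drug present) and P(event | absent), exact.

    Enumerates the joint presence of every *other* drug carrying a
    multiplier for the term (drugs are independent in the generator).
    """
    tspec = next(t for t in config.terms if t.pt_code == term)
    lam_target = config.signals.get((drug, term), 1.0)
    others = [(s.marginal, config.signals[(s.name, term)])
              for s in config.drugs
              if s.name != drug and config.signals.get((s.name, term), 1.0) != 1.0]

    def prob(target_present: bool) -> float:
        total = 0.0
        for mask in range(2 ** len(others)):
            p = 1.0
            rate = tspec.baseline * (lam_target if target_present else 1.0)
            for j, (mo, lo) in enumerate(others):
                if mask >> j & 1:
                    p *= mo
                    rate *= lo
                else:
                    p *= 1 - mo
            total += p * min(1.0, rate)
        return total

    return prob(True), prob(False)


def _ground_truth(config: SyntheticConfig) -> GroundTruth:
    pairs = {}
    for (drug, term), lam in config.signals.items():
        spec = next(s for s in config.drugs if s.name == drug)
        e = spec.marginal * spec.role_probs.get("suspected", 0.0)
        m = spec.marginal
        p_present, p_absent = _event_probs(config, drug, term)
        p_unexposed = (((1 - m) * p_absent + (m - e) * p_present) / (1 - e)
                       if e < 1 else math.nan)
        cells = {
            "p_a": e * p_present,
            "p_b": e * (1 - p_present),
            "p_c": (1 - e) * p_unexposed,
        }
        cells["p_d"] = 1 - cells["p_a"] - cells["p_b"] - cells["p_c"]
        pairs[(drug, term)] = {
            "lambda": lam,
            "expected_prr": expected_prr(config, drug, term),
            "cells": cells,
            "weibull": config.onset.get((drug, term)),
        }
    return GroundTruth(pairs=pairs)


def generate_frames(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame],
                                                      GroundTruth]:
    """Draw the four tables as DataFrames of strings (pre-CSV form)."""
    rng = _streams(config.seed)
    n = config.n_reports
    case_ids = np.array([f"C{i:07d}" for i in range(n)])
    epoch = pd.Timestamp(config.start_epoch)

    demo = pd.DataFrame({
        "case_id": case_ids,
        "version": np.ones(n, dtype=int),
        "sex": _categorical(rng["demo"], config.sex_probs, n),
        "age_band": _categorical(rng["demo"], config.age_probs, n),
        "weight_band": _categorical(rng["demo"], config.weight_probs, n),
    })

    # drug presence / role / route, vectorised per drug; every drug entry
    # of a report shares the report's therapy start date
    start_offsets = rng["drug"].integers(0, config.start_window_days, size=n)
    starts = epoch + pd.to_timedelta(start_offsets, unit="D")
    drug_parts = []
    presence: dict[str, np.ndarray] = {}
    for spec in config.drugs:
        present = rng["drug"].random(n) < spec.marginal
        presence[spec.name] = present
        idx = np.nonzero(present)[0]
        roles = _categorical(rng["drug"], spec.role_probs, len(idx))
        routes = _categorical(rng["drug"], spec.route_probs, len(idx))
        durations = rng["drug"].geometric(1.0 / config.mean_duration_days,
                                          size=len(idx))
        drug_parts.append(pd.DataFrame({
            "case_id": case_ids[idx],
            "version": 1,
            "drug_name": spec.name,
            "role": roles,
            "route": routes,
            "start_date": pd.Series(starts[idx]),
            "end_date": pd.Series(starts[idx] + pd.to_timedelta(durations,
                                                                unit="D")),
        }))
    drug_cols = ["case_id", "version", "drug_name", "role", "route",
                 "start_date", "end_date"]
    drug = (pd.concat(drug_parts, ignore_index=True) if drug_parts
            else pd.DataFrame(columns=drug_cols))
    if drug.empty:
        drug = pd.DataFrame(columns=drug_cols)

    # events: per term, rate = baseline * prod(lambda over present signal
    # drugs); TTO anchored to the first (config order) present drug with a
    # planted onset for the term, else the background Weibull
    reac_parts = []
    for tspec in config.terms:
        rate = np.full(n, tspec.baseline)
        for spec in config.drugs:
            lam = config.signals.get((spec.name, tspec.pt_code), 1.0)
            if lam != 1.0:
                rate = np.where(presence[spec.name], rate * lam, rate)
        occurs = rng["event"].random(n) < np.minimum(rate, 1.0)
        idx = np.nonzero(occurs)[0]
        if len(idx) == 0:
            continue
        a0, b0 = config.background_onset
        tto = a0 * rng["onset"].weibull(b0, size=len(idx))
        assigned = np.zeros(len(idx), dtype=bool)
        for spec in config.drugs:
            params = config.onset.get((spec.name, tspec.pt_code))
            if params is None:
                continue
            sel = presence[spec.name][idx] & ~assigned
            if sel.any():
                a1, b1 = params
                tto[sel] = a1 * rng["onset"].weibull(b1, size=int(sel.sum()))
                assigned |= sel
        days = np.maximum(1, np.ceil(tto)).astype(int)
        reac_parts.append(pd.DataFrame({
            "case_id": case_ids[idx],
            "version": 1,
            "pt_code": tspec.pt_code,
            "onset_date": pd.Series(starts[idx]
                                    + pd.to_timedelta(days - 1, unit="D")),
        }))
    reac_cols = ["case_id", "version", "pt_code", "onset_date"]
    reac = (pd.concat(reac_parts, ignore_index=True) if reac_parts
            else pd.DataFrame(columns=reac_cols))

    hist = pd.DataFrame({
        "case_id": case_ids[rng["demo"].random(n) < 0.3],
        "term": "chronic_condition",
    })
    hist.insert(1, "version", 1)
    hist = hist[["case_id", "version", "term"]]

    def fmt_dates(series: pd.Series, rng_missing) -> pd.Series:
        if series.empty:
            return series.astype(str)
        series = pd.to_datetime(series)
        out = series.dt.strftime("%Y-%m-%d")
        if config.date_missing_fraction > 0:
            u = rng_missing.random(len(out))
            blank = u < config.date_missing_fraction / 2
            trunc = (~blank) & (u < config.date_missing_fraction)
            out = out.where(~blank, "")
            out = out.where(~trunc, series.dt.strftime("%Y-%m"))
        return out

    for col in ("start_date", "end_date"):
        drug[col] = fmt_dates(drug[col], rng["missing"])
    reac["onset_date"] = fmt_dates(reac["onset_date"], rng["missing"])

    frames = {"DEMO": demo, "DRUG": drug, "REAC": reac, "HIST": hist}

    # duplicates: extra identical version-2 rows for a sampled set of cases
    if config.duplicate_fraction > 0 and n > 0:
        k = int(round(config.duplicate_fraction * n))
        dup_cases = set(case_ids[rng["duplicate"].choice(n, size=k,
                                                         replace=False)])
        for name, frame in frames.items():
            extra = frame[frame["case_id"].isin(dup_cases)].copy()
            extra["version"] = 2
            frames[name] = pd.concat([frame, extra], ignore_index=True)
        logger.info("injected %d duplicate case version(s)", k)
    for frame in frames.values():
        frame.sort_values(["case_id", "version"], inplace=True,
                          kind="stable", ignore_index=True)
    return frames, _ground_truth(config)


def generate(config: SyntheticConfig, outdir) -> tuple[dict[str, Path],
                                                       GroundTruth]:
    """Write DEMO/DRUG/REAC/HIST CSVs plus ground_truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, truth = generate_frames(config)
    paths = {}
    for name, frame in frames.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    paths["ground_truth"] = truth_path
    logger.info("synthetic database written to %s (%d reports)", outdir,
                config.n_reports)
    return paths, truth
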