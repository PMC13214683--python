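"""Tabular and graphical outputs: signal tables, volcano plots, TTO summaries.

Figures are rendered from the exported coordinate CSVs, never from
internal state, so every plot is reproducible from the artifacts alone.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .disproportionality import SignalResult, volcano_data
from .time_to_onset import TTOSample, WeibullFit, tto_boxplot_data

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["drug", "term_id", "level", "a", "drug_total", "c",
                  "nondrug_total", "prr", "chi2", "ror", "ror_ci_low",
                  "ror_ci_high", "ic", "ic025", "log_p", "log_fdr_p",
                  "reporting_ratio", "is_signal"]


def signal_table(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten screen results into the standard signal-table layout."""
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "term_id": r.term_id, "level": r.level,
            "a": r.table.a, "drug_total": r.table.drug_total,
            "c": r.table.c, "nondrug_total": r.table.nondrug_total,
            "prr": r.prr, "chi2": r.chi2, "ror": r.ror,
            "ror_ci_low": r.ror_ci[0], "ror_ci_high": r.ror_ci[1],
            "ic": r.ic, "ic025": r.ic025, "log_p": r.log_p,
            "log_fdr_p": r.log_fdr_p, "reporting_ratio": r.reporting_ratio,
            "is_signal": r.is_signal,
        })
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def write_signal_table(results: Sequence[SignalResult], path) -> Path:
    path = Path(path)
    signal_table(results).to_csv(path, index=False, float_format="%.10g")
    return path


def volcano_table(results: Sequence[SignalResult]) -> pd.DataFrame:
    rows = volcano_data(results)
    return pd.DataFrame(rows, columns=["log2_prr", "chi2", "reporting_ratio",
                                       "label"])


def write_volcano(results: Sequence[SignalResult], csv_path,
                  figure_path=None) -> Path:
    """Export volcano coordinates; optionally render the figure from the CSV."""
    csv_path = Path(csv_path)
    volcano_table(results).to_csv(csv_path, index=False, float_format="%.10g")
    if figure_path is not None:
        render_volcano(csv_path, figure_path)
    return csv_path


def render_volcano(csv_path, figure_path, title: str = "") -> Path:
    frame = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(6, 5))
    if len(frame):
        size = 20 + 600 * frame["reporting_ratio"]
        ax.scatter(frame["log2_prr"], frame["chi2"], s=size, alpha=0.55,
                   edgecolor="k", linewidth=0.3)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")   # PRR = 2
    ax.axhline(4.0, color="grey", lw=0.8, ls="--")   # chi2 = 4
    ax.set_xlabel(r"$\log_2$ PRR")
    ax.set_ylabel(r"$\chi^2$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    figure_path = Path(figure_path)
    fig.savefig(figure_path)
    plt.close(fig)
    return figure_path


WEIBULL_COLUMNS = ["drug", "term_id", "n", "median", "q1", "q3",
                   "alpha", "alpha_ci_low", "alpha_ci_high",
                   "beta", "beta_ci_low", "beta_ci_high",
                   "failure_type", "ad_p"]


def weibull_table(fits: Sequence[tuple[TTOSample, WeibullFit]]) -> pd.DataFrame:
    """Time-to-onset summary table; NA for groups below the fitting floor."""
    rows = []
    for sample, fit in fits:
        rows.append({
            "drug": sample.drug, "term_id": sample.term_id, "n": fit.n,
            "median": fit.median, "q1": fit.iqr[0], "q3": fit.iqr[1],
            "alpha": fit.alpha, "alpha_ci_low": fit.alpha_ci[0],
            "alpha_ci_high": fit.alpha_ci[1], "beta": fit.beta,
            "beta_ci_low": fit.beta_ci[0], "beta_ci_high": fit.beta_ci[1],
            "failure_type": (fit.failure_type if fit.evaluable else "NA"),
            "ad_p": fit.ad_p,
        })
    return pd.DataFrame(rows, columns=WEIBULL_COLUMNS)


def write_weibull_table(fits, path) -> Path:
    path = Path(path)
    weibull_table(fits).to_csv(path, index=False, float_format="%.10g",
                               na_rep="NA")
    return path


def write_tto_samples(samples: Sequence[TTOSample], path) -> Path:
    rows = [(s.drug, s.term_id, rid, day)
            for s in samples for rid, day in zip(s.report_ids, s.days)]
    path = Path(path)
    pd.DataFrame(rows, columns=["drug", "term_id", "report_id", "days"]) \
        .to_csv(path, index=False)
    return path


def write_boxplot(samples: Sequence[TTOSample], csv_path,
                  figure_path=None) -> Path:
    """Export Tukey boxplot statistics; optionally render from the CSV."""
    stats = tto_boxplot_data(list(samples))
    frame = pd.DataFrame(stats)
    if not len(frame):
        frame = pd.DataFrame(columns=["drug", "term_id", "n", "median", "q1",
                                      "q3", "whisker_low", "whisker_high",
                                      "outliers"])
    csv_path = Path(csv_path)
    frame.to_csv(csv_path, index=False)
    if figure_path is not None and len(frame):
        render_boxplot(csv_path, figure_path)
    return csv_path


def render_boxplot(csv_path, figure_path) -> Path:
    frame = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(frame)), 5))
    stats = []
    for _, row in frame.iterrows():
        stats.append({
            "med": row["median"], "q1": row["q1"], "q3": row["q3"],
            "whislo": row["whisker_low"], "whishi": row["whisker_high"],
            "fliers": [], "label": f"{row['drug']}\n{row['term_id']}",
        })
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("days from treatment initiation")
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    figure_path = Path(figure_path)
    fig.savefig(figure_path)
    plt.close(fig)
    return figure_path
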