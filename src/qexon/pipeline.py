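"""Per-chromosome and per-genome orchestration of the full analysis.

Stage order: series -> binned density -> autocorrelation -> two-timescale fit
-> windows at T -> xi(t) -> mixing fits -> marginal LM fits (both q-families)
-> nested-sampling evidences -> Bayes factor.  Stages that fail are recorded
with diagnostics without aborting later independent stages where possible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import __version__ as _version
from .annotation_io import ExonSeries, build_series, parse_exons, read_series
from .bayes_compare import (
    BayesComparison,
    bayes_factor,
    compute_evidence,
    priors_from_fit,
)
from .errors import QexonError, SkipWindow, ValidationError
from .local_windows import fit_local, fit_mixing, segment, xi_series
from .qdistributions import InvQGammaParams, QGammaParams, fit_marginal
from .series_stats import autocorrelation, binned_density, fit_two_exponential

logger = logging.getLogger("qexon")

__all__ = ["RunConfig", "ChromosomeReport", "GenomeReport",
           "run_chromosome", "run_genome", "load_series"]


@dataclass(frozen=True)
class RunConfig:
    input_path: str | None = None
    input_format: str = "auto"          # gff3 | tsv | auto
    chromosomes: tuple[str, ...] | None = None
    binning: str = "paper_linear_box"
    tau_max: int | None = None          # default: min(n // 10, 2000)
    fit_range: tuple[int, int] | None = None
    window_T: float | None = None       # default: fitted t2
    min_exons: int = 200
    fit_mode: str = "A_constrained"
    residual_scale: str = "linear"
    dedup: bool = False
    with_evidence: bool = True
    evidence_max_points: int = 2000
    nlive: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosomes"] = list(self.chromosomes) if self.chromosomes else None
        return d


@dataclass
class ChromosomeReport:
    chromosome: str
    n_exons: int
    seed: int
    provenance: dict = field(default_factory=dict)
    timescales: dict | None = None
    local_fits: dict | None = None
    mixing_fits: dict | None = None
    marginal_fits: dict | None = None
    comparison: dict | None = None
    warnings: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    @property
    def q_gamma(self) -> float | None:
        if self.marginal_fits and "q_gamma" in self.marginal_fits:
            return self.marginal_fits["q_gamma"]["q"]
        return None

    @property
    def q_inv_gamma(self) -> float | None:
        if self.marginal_fits and "inv_q_gamma" in self.marginal_fits:
            return self.marginal_fits["inv_q_gamma"]["q"]
        return None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, default=_jsonable)

    def table_row(self) -> dict:
        """Row shaped like the per-chromosome evidence/Bayes-factor tables."""
        row: dict[str, Any] = {"chromosome": self.chromosome}
        if self.comparison:
            row.update({k: self.comparison[k] for k in
                        ("ln_e1", "ln_e1_err", "ln_e2", "ln_e2_err",
                         "ln_B12", "ln_B12_err", "label")})
        row["q_gamma"] = self.q_gamma
        row["q_inv_gamma"] = self.q_inv_gamma
        return row


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    return str(o)


def load_series(config: RunConfig, chromosome: str | None = None) -> list[ExonSeries]:
    """Load one or more series from the configured input file."""
    path = config.input_path
    if path is None:
        raise ValidationError("config.input_path is not set")
    fmt = config.input_format
    if fmt == "auto":
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "gff3"
    if fmt == "tsv":
        s = read_series(path, chromosome=chromosome)
        return [s]
    records = parse_exons(path,
                          chromosome_filter=set(config.chromosomes)
                          if config.chromosomes else None)
    chroms = ([chromosome] if chromosome else
              list(dict.fromkeys(r.chromosome for r in records)))
    return [build_series(records, c, dedup=config.dedup) for c in chroms]


def _provenance(series: ExonSeries, config: RunConfig) -> dict:
    digest = hashlib.sha256(series.lengths.tobytes()).hexdigest()[:16]
    return {"input_hash": digest, "config": config.to_dict(),
            "qexon_version": _version, "n_exons": series.n}


def run_chromosome(config: RunConfig, chromosome: str | None = None,
                   series: ExonSeries | None = None) -> ChromosomeReport:
    """Full single-chromosome analysis; returns a structured report.

    Either pass a pre-built ``series`` or let the config's input be loaded.
    Chromosomes with fewer than ``config.min_exons`` exons are skipped (the
    report carries the reason and no fitted stages).
    """
    if series is None:
        series = load_series(config, chromosome)[0]
    report = ChromosomeReport(chromosome=series.chromosome, n_exons=series.n,
                              seed=config.seed,
                              provenance=_provenance(series, config))
    if series.n < config.min_exons:
        report.warnings.append(
            f"skipped: {series.n} exons < minimum {config.min_exons}")
        return report

    density = binned_density(series, scheme=config.binning)

    # --- timescales ---------------------------------------------------------
    T = config.window_T
    try:
        tau_max = config.tau_max or min(series.n // 10, 2000)
        corr = autocorrelation(series, tau_max)
        ts = fit_two_exponential(corr, fit_range=config.fit_range)
        report.timescales = {"a": ts.a, "b": ts.b, "t1": ts.t1, "t2": ts.t2,
                             "ratio": ts.ratio, "fit_rss": ts.fit_rss,
                             "scale_separated": ts.scale_separated}
        if not ts.scale_separated:
            report.warnings.append(
                f"no scale separation: t2/t1 = {ts.ratio:.2f} < 10")
        if T is None:
            T = ts.t2
    except QexonError as exc:
        report.failures["timescales"] = str(exc)
        logger.warning("%s: timescale stage failed: %s", series.chromosome, exc)

    # --- windows, local and mixing fits ------------------------------------
    if T is not None and round(T) >= 2 and round(T) <= series.n:
        report.local_fits = {}
        report.mixing_fits = {}
        for fam, mix_fam, key in (("gamma", "inverse_gamma", "gamma"),
                                  ("inverse_gamma", "gamma", "inverse_gamma")):
            try:
                fits = []
                for w in segment(series, T):
                    try:
                        fits.append(fit_local(w, fam))
                    except SkipWindow:
                        continue
                if fits:
                    shapes = [getattr(f, "k", getattr(f, "alpha", None))
                              for f in fits]
                    report.local_fits[key] = {
                        "n_windows_fit": len(fits),
                        "shape_median": float(np.median(shapes)),
                        "xi_median": float(np.median([f.xi for f in fits])),
                    }
                xis = xi_series(series, T, fam)
                mix = fit_mixing(xis, mix_fam)
                report.mixing_fits[key] = {
                    "mixing_family": mix_fam, "n_windows": xis.n_windows,
                    **{k: float(v) for k, v in asdict(mix).items()},
                }
            except QexonError as exc:
                report.failures[f"windows_{fam}"] = str(exc)
    else:
        report.failures.setdefault(
            "windows", "no usable window scale T (timescale fit failed?)")

    # --- marginal fits ------------------------------------------------------
    report.marginal_fits = {}
    for fam in ("q_gamma", "inv_q_gamma"):
        try:
            fit = fit_marginal(density, fam, mode=config.fit_mode,
                               residual_scale=config.residual_scale)
            p = fit.params
            report.marginal_fits[fam] = {
                "A": p.A, "shape": getattr(p, "a", getattr(p, "alpha", None)),
                "sigma": p.sigma, "q": p.q, "rss": fit.rss,
                "n_points": fit.n_points, "mode": fit.mode,
            }
        except QexonError as exc:
            report.failures[f"marginal_{fam}"] = str(exc)

    # --- evidence and Bayes factor ------------------------------------------
    if config.with_evidence:
        try:
            # priors centered on each family's own LM fit (sd = 10% of mean),
            # the same construction as the documented defaults
            pri1 = pri2 = None
            if report.marginal_fits.get("q_gamma"):
                m = report.marginal_fits["q_gamma"]
                pri1 = priors_from_fit(
                    QGammaParams(A=m["A"], a=m["shape"], sigma=m["sigma"],
                                 q=m["q"]), "q_gamma")
            if report.marginal_fits.get("inv_q_gamma"):
                m = report.marginal_fits["inv_q_gamma"]
                pri2 = priors_from_fit(
                    InvQGammaParams(A=m["A"], alpha=m["shape"],
                                    sigma=m["sigma"], q=m["q"]), "inv_q_gamma")
            if pri1 is None or pri2 is None:
                raise ValidationError(
                    "evidence skipped: no marginal fit to center priors on")
            e1 = compute_evidence(series, "q_gamma", priors=pri1,
                                  nlive=config.nlive, seed=config.seed,
                                  max_points=config.evidence_max_points)
            e2 = compute_evidence(series, "inv_q_gamma", priors=pri2,
                                  nlive=config.nlive, seed=config.seed + 1,
                                  max_points=config.evidence_max_points)
            cmp_ = bayes_factor(e1, e2)
            report.comparison = {
                "ln_e1": cmp_.ln_e1, "ln_e1_err": cmp_.ln_e1_err,
                "ln_e2": cmp_.ln_e2, "ln_e2_err": cmp_.ln_e2_err,
                "ln_B12": cmp_.ln_B12, "ln_B12_err": cmp_.ln_B12_err,
                "label": cmp_.label,
                "n_points": e1.sampler_settings.get("n_data"),
            }
        except QexonError as exc:
            report.failures["evidence"] = str(exc)
    return report


@dataclass
class GenomeReport:
    chromosomes: list[ChromosomeReport]
    aggregate: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"aggregate": self.aggregate,
                "chromosomes": [r.to_dict() for r in self.chromosomes],
                "failures": self.failures}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, default=_jsonable)


def _mean_se(values: list[float]) -> dict:
    arr = np.asarray(values, float)
    out = {"mean": float(arr.mean()), "n": int(arr.size)}
    out["se"] = (float(arr.std(ddof=1) / np.sqrt(arr.size))
                 if arr.size > 1 else None)
    return out


def run_genome(config: RunConfig,
               series_list: list[ExonSeries] | None = None) -> GenomeReport:
    """Analyze every chromosome and aggregate the entropic indices.

    The aggregate reports the unweighted mean of the fitted q across
    chromosomes with its standard error (absent for a single chromosome).
    """
    if series_list is None:
        series_list = load_series(config)
    reports, failures = [], []
    for s in series_list:
        try:
            reports.append(run_chromosome(config, series=s))
        except QexonError as exc:
            failures.append({"chromosome": s.chromosome, "error": str(exc)})
    if not reports:
        raise ValidationError("all chromosomes failed")
    agg = {}
    qg = [r.q_gamma for r in reports if r.q_gamma is not None]
    qig = [r.q_inv_gamma for r in reports if r.q_inv_gamma is not None]
    if qg:
        agg["q_gamma"] = _mean_se(qg)
    if qig:
        agg["q_inv_gamma"] = _mean_se(qig)
    return GenomeReport(chromosomes=reports, aggregate=agg, failures=failures)
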