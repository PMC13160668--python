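"""Validation, trend projection, and end-to-end pipeline orchestration.

External validation correlates per-keyword mean relative citation ratio
(RCR) with network strength (Spearman, permutation p). RCR is strictly
post-hoc: nothing upstream (selection, embedding, clustering) reads it.
The trend projection fits a small ARIMA grid to the annual publication
series and forecasts the next year with a 95% prediction interval.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import bursts as bursts_mod
from . import slices as slices_mod
from .clustering import (
    DEFAULT_SEEDS,
    cluster_hdbscan,
    internal_metrics,
    reduce_umap,
)
from .coupling import coupling_report
from .network import CoocNetwork, KeywordStats, build_cooc, keyword_frequencies, select_keywords
from .records import BibRecord, write_jsonl
from .semantics import HashedProjectionBackend, build_hybrid
from .strategy import classify_octant, compute_axes, default_thresholds
from .synthcorpus import default_config, generate_corpus

__all__ = [
    "ValidationReport",
    "TrendProjection",
    "rcr_correlation",
    "arima_projection",
    "run_pipeline",
    "DEFAULT_CONFIG",
]


@dataclass
class ValidationReport:
    rcr_spearman_rho: Optional[float] = None
    rcr_permutation_p: Optional[float] = None
    cluster_mean_rcr: dict[int, float] = field(default_factory=dict)
    n_keywords: int = 0
    n_permutations: int = 0
    seeds: list[int] = field(default_factory=list)
    skipped_reason: Optional[str] = None


@dataclass
class TrendProjection:
    annual_counts: dict[int, int]
    forecast_year: int
    point_forecast: float
    pi95: tuple[float, float]
    model_order: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, hi = self.pi95
        if not lo <= self.point_forecast <= hi:
            raise ValueError("prediction interval must contain the point forecast")


def rcr_correlation(
    stats: list[KeywordStats],
    net: CoocNetwork,
    corpus: list[BibRecord],
    labels: Optional[dict[str, int]] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> ValidationReport:
    """Spearman correlation of keyword network strength with per-keyword mean
    RCR, with a two-sided permutation p-value (strength vector permuted).

    Requires >= 10 keywords backed by at least one RCR-bearing record;
    otherwise the stage is skipped with an explicit reason.
    """
    rcr_by_record = {r.record_id: r.rcr for r in corpus if r.rcr is not None}
    if not rcr_by_record:
        return ValidationReport(skipped_reason="external validation unavailable: no RCR data")
    kw_rcrs: dict[str, list[float]] = {}
    for rec in corpus:
        if rec.rcr is None:
            continue
        for kw in set(rec.author_keywords):
            kw_rcrs.setdefault(kw, []).append(rec.rcr)
    keywords = [k for k in net.nodes if k in kw_rcrs]
    if len(keywords) < 10:
        return ValidationReport(
            skipped_reason=f"external validation unavailable: only {len(keywords)} "
            "keywords with RCR-bearing records (need >= 10)"
        )
    mean_rcr = np.array([float(np.mean(kw_rcrs[k])) for k in keywords])
    strength = np.array([net.strength(k) for k in keywords])
    rho = float(spearmanr(strength, mean_rcr).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(strength)
        r = spearmanr(perm, mean_rcr).statistic
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    report = ValidationReport(
        rcr_spearman_rho=rho,
        rcr_permutation_p=p,
        n_keywords=len(keywords),
        n_permutations=n_permutations,
    )
    if labels:
        sums: dict[int, list[float]] = {}
        for k in keywords:
            c = labels.get(k)
            if c is not None:
                sums.setdefault(c, []).extend(kw_rcrs[k])
        report.cluster_mean_rcr = {c: float(np.mean(v)) for c, v in sorted(sums.items())}
    return report


def arima_projection(
    annual_counts: dict[int, int],
    forecast_year: int,
) -> TrendProjection:
    """One-step forecast of the annual publication count.

    The model order is chosen by AIC over (p, d, q) in {0,1,2}x{0,1}x{0,1},
    fit on complete years strictly before ``forecast_year`` (the incomplete
    final year never enters the fit). The forecast and interval are floored
    at 0. A constant series degenerates to a mean forecast with a
    residual-based interval.
    """
    years = sorted(y for y in annual_counts if y < forecast_year)
    if len(years) < 6:
        raise ValueError(f"need >= 6 complete years before {forecast_year}, have {len(years)}")
    series = np.array([annual_counts[y] for y in years], dtype=float)

    if np.allclose(series, series[0]):
        mean = float(series[0])
        return TrendProjection(
            annual_counts=dict(annual_counts),
            forecast_year=forecast_year,
            point_forecast=mean,
            pi95=(max(mean - 1.96, 0.0), mean + 1.96),
            model_order=(0, 0, 0),
        )

    from statsmodels.tsa.arima.model import ARIMA

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in (0, 1, 2):
            for d in (0, 1):
                for q in (0, 1):
                    if p == d == q == 0:
                        continue
                    try:
                        # drift under differencing; constant for stationary fits
                        fit = ARIMA(
                            series, order=(p, d, q), trend="t" if d == 1 else "c"
                        ).fit()
                    except Exception:
                        continue
                    if best is None or fit.aic < best[0]:
                        best = (fit.aic, (p, d, q), fit)
        if best is None:
            raise RuntimeError("no ARIMA model could be fit")
        _, order, fit = best
        fc = fit.get_forecast(steps=1)
        point = float(fc.predicted_mean[0])
        ci = fc.conf_int(alpha=0.05)
        lo, hi = float(ci[0, 0]), float(ci[0, 1])
    point = max(point, 0.0)
    lo = min(max(lo, 0.0), point)
    hi = max(hi, point)
    return TrendProjection(
        annual_counts=dict(annual_counts),
        forecast_year=forecast_year,
        point_forecast=point,
        pi95=(lo, hi),
        model_order=order,
    )


# ---------------------------------------------------------------------------
# pipeline orchestration

DEFAULT_CONFIG: dict = {
    "corpus": {"path": None, "format": "jsonl", "synthetic": True, "seed": 0,
               "n_records": 300, "n_topics": 5},
    "window": [2015, 2025],
    "network": {"min_freq": 3, "drop_top": 2, "weighting": "fractional"},
    "embedding": {"alpha": 0.5, "dimension": 256, "seed": 0},
    "clustering": {"profile": "balanced", "n_neighbors": 15, "min_dist": 0.1,
                   "seeds": list(DEFAULT_SEEDS)},
    "strategy": {"recent_window": 5, "z_mode": "fixed"},
    "coupling": {"top_k": 5},
    "bursts": {"gammas": [0.3, 0.5, 1.0], "windows": [1, 3], "min_lengths": [1],
               "baseline": "G0.5_W3_L1"},
    "slices": {"boundaries": [list(b) for b in slices_mod.DEFAULT_SLICES],
               "k_min": 2, "k_max": 20, "jaccard_threshold": 0.3},
    "validation": {"n_permutations": 999},
    "seed": 42,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _fingerprint(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Optional[dict] = None, out_dir: str | Path = "artifacts") -> dict:
    """Execute the full pipeline: ingest/simulate -> normalize -> network ->
    hybrid similarity -> clustering -> strategic map -> coupling -> bursts ->
    slices -> validation, writing every stage's CSV artifacts plus a JSONL
    run log under ``out_dir``.

    With the offline embedding backend and fixed seeds, two runs with the
    same config produce identical artifacts (the run log carries the only
    timestamps). Returns a summary dict.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    for key in ("corpus", "network", "embedding", "clustering", "strategy",
                "coupling", "bursts", "slices", "validation"):
        if not isinstance(config.get(key), dict):
            raise KeyError(f"config missing required key {key!r}")
    if not isinstance(config.get("window"), (list, tuple)) or len(config["window"]) != 2:
        raise KeyError("config missing required key 'window'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w", encoding="utf-8")
    fingerprint = _fingerprint(config)

    def log(stage: str, **kw) -> None:
        entry = {"stage": stage, "time": time.time(), "fingerprint": fingerprint, **kw}
        log_fh.write(json.dumps(entry, default=str) + "\n")
        log_fh.flush()

    summary: dict = {"fingerprint": fingerprint, "out_dir": str(out)}
    stage = "ingest"
    try:
        # --- ingest or simulate
        window = tuple(config["window"])
        ccfg = config["corpus"]
        if ccfg.get("path"):
            from .records import filter_complete, normalize_keywords, parse_records

            corpus, _rep = parse_records(ccfg["path"], ccfg.get("format", "jsonl"))
        else:
            synth = default_config(
                n_records=ccfg.get("n_records", 300),
                n_topics=ccfg.get("n_topics", 5),
                years=window,
                seed=ccfg.get("seed", 0),
                rcr_gradient=True,
            )
            corpus, truth = generate_corpus(synth)
            pd.DataFrame(
                sorted(truth["record_topic"].items()), columns=["record_id", "topic_id"]
            ).to_csv(out / "ground_truth_records.csv", index=False)
        from .records import filter_complete, normalize_keywords

        corpus = normalize_keywords(corpus)
        corpus, counts = filter_complete(corpus, window)
        write_jsonl(corpus, out / "corpus.jsonl")
        log(stage, n_retained=counts.n_retained, n_retrieved=counts.n_retrieved)

        # --- network
        stage = "network"
        ncfg = config["network"]
        ref_year = window[1]
        stats = keyword_frequencies(
            corpus, window=window,
            recent_window=config["strategy"]["recent_window"],
            reference_year=ref_year,
        )
        retained, sel_log = select_keywords(stats, ncfg["min_freq"], ncfg["drop_top"])
        net = build_cooc(corpus, retained, ncfg["weighting"])
        net.write(out)
        log(stage, **sel_log)

        # --- semantics
        stage = "semantics"
        ecfg = config["embedding"]
        backend = HashedProjectionBackend(ecfg["dimension"], ecfg["seed"])
        hybrid, hyb_log = build_hybrid(corpus, net, [backend], ecfg["alpha"])
        pd.DataFrame(hybrid.s_hyb, index=hybrid.keywords, columns=hybrid.keywords).to_csv(
            out / "hybrid_similarity.csv", float_format="%.6f"
        )
        log(stage, **{k: v for k, v in hyb_log.items() if not isinstance(v, list)})

        # --- clustering (multi-seed)
        stage = "clustering"
        kcfg = config["clustering"]
        runs = []
        for s in kcfg["seeds"]:
            coords = reduce_umap(hybrid, kcfg["n_neighbors"], kcfg["min_dist"], seed=s)
            runs.append(cluster_hdbscan(coords, hybrid.keywords, kcfg["profile"], seed=s))
        solution = runs[0]
        solution.write(out / "clusters.csv")
        metrics = internal_metrics(solution.coords2d, solution.labels, runs)
        log(stage, n_thematic=solution.n_thematic,
            silhouette=metrics.silhouette, ari_across_seeds=metrics.ari_across_seeds)

        # --- strategy
        stage = "strategy"
        scfg = config["strategy"]
        coords = compute_axes(stats, net, scfg["recent_window"], ref_year)
        taxonomy = default_thresholds(coords, scfg["z_mode"])
        strategic = classify_octant(coords, taxonomy)
        labels_map = solution.label_map()
        strategic["cluster"] = [labels_map.get(k) for k in strategic["keyword"]]
        strategic.to_csv(out / "strategic_map.csv", index=False, float_format="%.6f")
        log(stage, y_threshold=taxonomy.y_threshold, z_threshold=taxonomy.z_threshold,
            z_mode=scfg["z_mode"],
            note="z plane uses the reference-point convention (0.5); the mean-z "
                 "plane is available via z_mode='mean'")

        # --- coupling
        stage = "coupling"
        creport = coupling_report(net, labels_map, config["coupling"]["top_k"])
        pd.DataFrame(
            [(a, b, s) for (a, b), s in sorted(creport.pair_strength.items())],
            columns=["cluster_a", "cluster_b", "strength"],
        ).to_csv(out / "coupling_pairs.csv", index=False, float_format="%.6f")
        pd.DataFrame(
            [
                (a, b, kw, src, c)
                for (a, b), rows in sorted(creport.bridging.items())
                for kw, src, c in rows
            ],
            columns=["cluster_a", "cluster_b", "keyword", "source_cluster", "contribution"],
        ).to_csv(out / "bridging.csv", index=False, float_format="%.6f")
        pd.DataFrame(
            sorted(creport.global_bridging.items()), columns=["keyword", "bridging_strength"]
        ).to_csv(out / "global_bridging.csv", index=False, float_format="%.6f")
        log(stage, n_pairs=len(creport.pair_strength), caveat=creport.noise_cluster_flag)

        # --- bursts
        stage = "bursts"
        bcfg = config["bursts"]
        configs = [
            bursts_mod.BurstConfig(gamma=g, window_w=w, min_length=l)
            for g in bcfg["gammas"] for w in bcfg["windows"] for l in bcfg["min_lengths"]
        ]
        grid = bursts_mod.robustness_grid(
            corpus, configs, bcfg["baseline"], min_freq=ncfg["min_freq"], window=window
        )
        baseline_cfg = next(c for c in configs if c.config_id == bcfg["baseline"])
        rows = []
        for kw in sorted(grid.burst_sets[bcfg["baseline"]]):
            series = bursts_mod.build_series(corpus, kw, baseline_cfg.window_w, window=window)
            for iv in bursts_mod.kleinberg_bursts(series, baseline_cfg):
                rows.append((kw, iv.start_year, iv.end_year, iv.level, iv.weight,
                             bcfg["baseline"]))
        pd.DataFrame(
            rows, columns=["keyword", "start", "end", "level", "weight", "config_id"]
        ).to_csv(out / "bursts.csv", index=False, float_format="%.6f")
        frames = grid.to_frames()
        frames["jaccard"].to_csv(out / "burst_grid_jaccard.csv", float_format="%.6f")
        frames["spearman"].to_csv(out / "burst_grid_spearman.csv", float_format="%.6f")
        log(stage, coverage=grid.coverage, realism=grid.realism,
            definitions=grid.definitions)

        # --- slices
        stage = "slices"
        slcfg = config["slices"]
        boundaries = tuple(tuple(b) for b in slcfg["boundaries"])
        slice_corpora, dropped = slices_mod.slice_corpus(corpus, boundaries)
        align_rows = []
        for bounds, sub in zip(boundaries, slice_corpora):
            tag = f"{bounds[0]}-{bounds[1]}"
            if not sub:
                log(stage, slice=tag, note="empty slice, skipped")
                continue
            sstats = keyword_frequencies(sub, window=bounds)
            try:
                sretained, _ = select_keywords(sstats, ncfg["min_freq"], ncfg["drop_top"])
            except ValueError as exc:
                log(stage, slice=tag, note=f"skipped: {exc}")
                continue
            if len(sretained) < 4:
                log(stage, slice=tag, note="too few keywords, skipped")
                continue
            snet = build_cooc(sub, sretained, ncfg["weighting"])
            k_hi = min(slcfg["k_max"], len(snet.nodes) - 1)
            k_star, scan, note = slices_mod.select_k(
                snet, range(slcfg["k_min"], k_hi + 1), seed=config["seed"]
            )
            slabels = slices_mod.spectral_cluster(snet, k_star, seed=config["seed"])
            pd.DataFrame(sorted(slabels.items()), columns=["keyword", "cluster"]).to_csv(
                out / f"slice_{tag}_labels.csv", index=False
            )
            scan.to_csv(out / f"slice_{tag}_scan.csv", index=False, float_format="%.6f")
            amap = slices_mod.align_to_global(
                slabels, solution, slcfg["jaccard_threshold"]
            )
            for row in amap.rows:
                align_rows.append({"slice": tag, **row})
            log(stage, slice=tag, K=k_star, note=note,
                config_fingerprint_shared_path=fingerprint)
        pd.DataFrame(align_rows).to_csv(out / "alignment.csv", index=False,
                                        float_format="%.6f")

        # --- validation
        stage = "validation"
        vreport = rcr_correlation(
            stats, net, corpus, labels_map,
            n_permutations=config["validation"]["n_permutations"],
            seed=config["seed"],
        )
        validation = {
            "rcr_spearman_rho": vreport.rcr_spearman_rho,
            "rcr_permutation_p": vreport.rcr_permutation_p,
            "cluster_mean_rcr": vreport.cluster_mean_rcr,
            "skipped_reason": vreport.skipped_reason,
            "silhouette": metrics.silhouette,
            "davies_bouldin": metrics.davies_bouldin,
            "ari_across_seeds": metrics.ari_across_seeds,
        }
        (out / "validation.json").write_text(json.dumps(validation, indent=2, default=str))
        log(stage, **{k: v for k, v in validation.items() if k != "cluster_mean_rcr"})

        # --- trend projection (final year treated as incomplete, excluded from fit)
        stage = "trend"
        annual = {
            y: sum(1 for r in corpus if r.year == y)
            for y in range(window[0], window[1] + 1)
        }
        try:
            proj = arima_projection(annual, forecast_year=window[1])
            trend = {
                "forecast_year": proj.forecast_year,
                "point_forecast": proj.point_forecast,
                "pi95": list(proj.pi95),
                "model_order": list(proj.model_order),
                "annual_counts": {str(y): n for y, n in sorted(annual.items())},
            }
            (out / "trend.json").write_text(json.dumps(trend, indent=2))
            log(stage, point_forecast=proj.point_forecast, order=proj.model_order)
        except ValueError as exc:
            log(stage, note=f"trend projection skipped: {exc}")

        summary.update(
            n_records=len(corpus),
            n_keywords=len(hybrid.keywords),
            n_thematic_clusters=solution.n_thematic,
            coverage=grid.coverage,
            validation=validation,
        )
        log("done")
    except Exception as exc:
        log("error", failed_stage=stage, error=str(exc))
        log_fh.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log_fh.close()
    return summary
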