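"""Exhaustive-scan oracle, detection bookkeeping, and Power / recall /
precision / F-measure summaries over replicated simulated datasets."""

from __future__ import annotations

import time
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .core import SearchConfig, SearchResult, SolutionRecord, run
from .episim import SimulationSpec, builtin_models, simulate_dataset
from .genotype_data import GenotypeDataset

__all__ = [
    "EvaluationSummary",
    "exhaustive_search",
    "detection_success",
    "summarize",
    "benchmark",
]

EXHAUSTIVE_GUARD = 10**6


@dataclass(frozen=True)
class EvaluationSummary:
    """Dataset-level detection counts and the derived ratios.

    Each simulated dataset embeds exactly one functional combination, so
    power (#T/#S) and recall coincide.  The F-measure is the harmonic
    mean of recall and precision, 0 by convention when either is 0.
    """

    n_datasets: int
    n_detected: int
    tp: int
    fn: int
    fp: int
    power: float
    recall: float
    precision: float
    f_measure: float


def exhaustive_search(ds: GenotypeDataset, k: int = 2) -> list[SolutionRecord]:
    """Score every k-subset of SNPs and rank by fitness (descending, ties
    broken lexicographically by combo).  The brute-force oracle against
    which the stochastic search is validated."""
    n_combos = comb(ds.n_snps, k)
    if n_combos > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"C({ds.n_snps}, {k}) = {n_combos} exceeds the exhaustive guard "
            f"of {EXHAUSTIVE_GUARD}"
        )
    g = np.ascontiguousarray(ds.genotypes, dtype=np.int64)
    y = np.ascontiguousarray(ds.phenotype, dtype=np.int64)
    n_cells = 3**k
    combos = list(combinations(range(ds.n_snps), k))
    counts = np.empty((n_combos, n_cells, 2), dtype=np.int64)
    for i, combo in enumerate(combos):
        code = np.zeros(len(y), dtype=np.int64)
        for c in combo:
            code = code * 3 + g[:, c]
        counts[i] = np.bincount(code * 2 + y, minlength=2 * n_cells).reshape(n_cells, 2)

    total = counts.sum(axis=(1, 2)).astype(float)
    row = counts.sum(axis=2)  # (n_combos, cells)
    col = counts.sum(axis=1)  # (n_combos, 2)

    def _h(w: np.ndarray) -> np.ndarray:
        p = w.reshape(w.shape[0], -1) / total[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        return -terms.sum(axis=1)

    mi = np.maximum(_h(row) + _h(col) - _h(counts), 0.0)
    k2 = (gammaln(row + 2) - gammaln(counts + 1).sum(axis=2)).sum(axis=1)
    fit = mi / np.maximum(k2, 1e-12)

    # Pearson chi-square over occupied rows, vectorized across combos
    occ = row > 0
    n_rows = occ.sum(axis=1)
    expected = row[:, :, None] * col[:, None, :] / total[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = contrib.sum(axis=(1, 2))
    df = np.maximum(n_rows - 1, 1)
    pvals = np.where(
        (n_rows < 2) | (col == 0).any(axis=1),
        1.0,
        np.clip(chi2.sf(stat, df), np.finfo(float).tiny, 1.0),
    )

    order = sorted(range(n_combos), key=lambda i: (-fit[i], combos[i]))
    return [
        SolutionRecord(
            combo=combos[i],
            mi=float(mi[i]),
            k2log=float(k2[i]),
            fit=float(fit[i]),
            p_value=float(pvals[i]),
        )
        for i in order
    ]


def detection_success(
    result: SearchResult | Sequence[SolutionRecord],
    truth: Sequence[int],
    top_k: int = 1,
) -> bool:
    """True iff ``truth`` (as an unordered set of SNP indices) appears
    among the first ``top_k`` ranked combinations."""
    ranked = result.ranked if isinstance(result, SearchResult) else list(result)
    target = frozenset(int(i) for i in truth)
    return any(frozenset(rec.combo) == target for rec in ranked[:top_k])


def summarize(
    detections: Sequence[bool],
    false_positive_flags: Optional[Sequence[bool]] = None,
) -> EvaluationSummary:
    """Aggregate per-dataset detection outcomes into Power = #T/#S,
    recall = #TP/(#TP+#FN), precision = #TP/(#TP+#FP), and the harmonic
    F-measure 2 / (1/recall + 1/precision)."""
    detections = [bool(d) for d in detections]
    if not detections:
        raise ValueError("summarize needs at least one dataset outcome")
    if false_positive_flags is None:
        false_positive_flags = [False] * len(detections)
    false_positive_flags = [bool(f) for f in false_positive_flags]
    if len(false_positive_flags) != len(detections):
        raise ValueError("detections and false_positive_flags must align")

    n = len(detections)
    tp = sum(detections)
    fn = n - tp
    fp = sum(false_positive_flags)
    power = tp / n
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    if recall > 0 and precision > 0:
        f_measure = 2.0 / (1.0 / recall + 1.0 / precision)
    else:
        f_measure = 0.0
    return EvaluationSummary(
        n_datasets=n,
        n_detected=tp,
        tp=tp,
        fn=fn,
        fp=fp,
        power=power,
        recall=recall,
        precision=precision,
        f_measure=f_measure,
    )


def _false_positive(
    ranked: Sequence[SolutionRecord],
    truth: Sequence[int],
    n_snps: int,
    k: int,
    alpha: float = 0.05,
) -> bool:
    """A confidently wrong top report: the top-1 combo is not the truth
    and its Bonferroni-corrected p-value (over all C(n_snps, k) tests)
    clears ``alpha``."""
    if not ranked:
        return False
    top = ranked[0]
    if frozenset(top.combo) == frozenset(int(i) for i in truth):
        return False
    return top.p_value * comb(n_snps, k) < alpha


def _run_method(ds: GenotypeDataset, method: str, cfg: SearchConfig) -> Sequence[SolutionRecord]:
    if method == "exhaustive":
        return exhaustive_search(ds, k=cfg.order)
    objective = {"sfmoabc": "multi", "abc_mi": "mi_only", "abc_k2": "k2_only"}[method]
    cfg = SearchConfig(
        n_sources=cfg.n_sources,
        max_iter=cfg.max_iter,
        limit=cfg.limit,
        m0=cfg.m0,
        n_links=cfg.n_links,
        order=cfg.order,
        seed=cfg.seed,
        objective=objective,
        top_k_report=cfg.top_k_report,
    )
    return run(ds, cfg).ranked


def benchmark(
    models: Sequence[str],
    n_replicates: int = 10,
    methods: Sequence[str] = ("sfmoabc", "exhaustive"),
    seed: int = 0,
    top_k: int = 1,
    spec_overrides: Optional[dict] = None,
    search_config: Optional[SearchConfig] = None,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` datasets per model, run each method, and
    tabulate the detection metrics (one tidy row per model x method).

    Replicate seeds derive deterministically from ``seed``; the same
    datasets are shared by every method.
    """
    registry = builtin_models()
    unknown = [m for m in models if m not in registry]
    if unknown:
        raise ValueError(f"unknown model labels {unknown}")
    bad = [m for m in methods if m not in ("sfmoabc", "abc_mi", "abc_k2", "exhaustive")]
    if bad:
        raise ValueError(f"unknown methods {bad}")
    overrides = dict(spec_overrides or {})
    base_cfg = search_config or SearchConfig()

    rows = []
    for mi_model, label in enumerate(models):
        datasets = []
        for rep in range(n_replicates):
            spec = SimulationSpec(
                model=registry[label],
                seed=(seed * 1_000_003 + mi_model * 1009 + rep) % 2**31,
                **overrides,
            )
            datasets.append(simulate_dataset(spec))
        for method in methods:
            detections, fps, secs = [], [], []
            for rep, ds in enumerate(datasets):
                cfg = SearchConfig(
                    n_sources=base_cfg.n_sources,
                    max_iter=base_cfg.max_iter,
                    limit=base_cfg.limit,
                    m0=base_cfg.m0,
                    n_links=base_cfg.n_links,
                    order=base_cfg.order,
                    seed=(seed * 7_919 + mi_model * 101 + rep) % 2**31,
                    objective=base_cfg.objective,
                    top_k_report=base_cfg.top_k_report,
                )
                t0 = time.perf_counter()
                ranked = _run_method(ds, method, cfg)
                secs.append(time.perf_counter() - t0)
                truth = ds.truth[0]
                detections.append(detection_success(list(ranked), truth, top_k=top_k))
                fps.append(_false_positive(ranked, truth, ds.n_snps, cfg.order))
            s = summarize(detections, fps)
            rows.append(
                {
                    "model": label,
                    "method": method,
                    "S": s.n_datasets,
                    "T": s.n_detected,
                    "TP": s.tp,
                    "FP": s.fp,
                    "FN": s.fn,
                    "power": s.power,
                    "recall": s.recall,
                    "precision": s.precision,
                    "f_measure": s.f_measure,
                    "mean_seconds": float(np.mean(secs)),
                }
            )
    return pd.DataFrame(rows)
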