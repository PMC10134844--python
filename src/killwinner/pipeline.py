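"""End-to-end orchestration: rates -> trade-off -> diversity -> classification."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classification_counts, classify_asvs, order_summary
from .diversity import composition_maintenance, diversity_table, diversity_vs_dilution
from .errors import InsufficientDataError, KillWinnerError, UndefinedCorrelationError
from .io import PipelineConfig
from .rates import estimate_rates
from .synthetic import TREATMENTS
from .tradeoff import permutation_null, tradeoff_lmm, tradeoff_table

log = logging.getLogger(__name__)

OUTPUT_TABLES = [
    "pngr.tsv", "pngr_fits.tsv", "trait_estimates.tsv", "community_qc.tsv",
    "tradeoff_by_experiment.tsv", "tradeoff_lmm.tsv", "permutation.tsv",
    "diversity.tsv", "diversity_lmm.tsv", "composition_distance.tsv",
    "composition_regressions.tsv", "ancova.tsv", "asv_classification.tsv",
    "order_summary.tsv",
]


def _child_seed(master: int, label: str) -> int:
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(label.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    densities: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run every analysis stage and (optionally) write the output tables.

    Returns a result bundle keyed like the output files. Stage failures are
    re-raised with a stage label so a broken input names its analysis.
    """
    cfg = config or PipelineConfig()
    results: dict = {"config": cfg}
    seeds = {name: _child_seed(cfg.seed, name) for name in ("diversity", "composition")}

    stage = "rates"
    try:
        rates = estimate_rates(counts, densities, metadata, duration_h=cfg.duration_h,
                               replicate_mode=cfg.replicate_mode,
                               subtraction_order=cfg.subtraction_order)
        results["pngr"] = rates["pngr"]
        results["pngr_fits"] = rates["fits"]
        results["trait_estimates"] = rates["traits"]
        results["community_qc"] = rates["community_qc"]

        stage = "tradeoff"
        results["tradeoff_by_experiment"] = tradeoff_table(rates["traits"])
        lmm_rows = []
        for cause in ("P", "PV", "V"):
            try:
                res = tradeoff_lmm(rates["traits"], cause)
            except (InsufficientDataError, UndefinedCorrelationError) as err:
                log.info("tradeoff LMM skipped for cause %s (%s)", cause, err)
                continue
            lmm_rows.append({"cause": cause, **dataclasses.asdict(res)})
        results["tradeoff_lmm"] = pd.DataFrame(lmm_rows)

        perm_rows, nulls = [], {}
        for cause in ("P", "PV", "V"):
            try:
                res = permutation_null(rates["pngr"], cause=cause, n_perm=cfg.n_perm,
                                       seed=_child_seed(cfg.seed, f"perm_{cause}"),
                                       perm_mode=cfg.perm_mode,
                                       subtraction_order=cfg.subtraction_order)
            except InsufficientDataError as err:
                log.info("permutation skipped for cause %s (%s)", cause, err)
                continue
            perm_rows.append(dict(cause=cause, observed_stat=res.observed_stat,
                                  null_mean=res.null_mean, null_sd=res.null_sd,
                                  shapiro_p=res.shapiro_p, z_score=res.z_score,
                                  z_p=res.z_p, empirical_p=res.empirical_p,
                                  stat_kind=res.stat_kind, n_perm=len(res.null_stats)))
            nulls[cause] = res.null_stats
        results["permutation"] = pd.DataFrame(perm_rows)
        results["permutation_nulls"] = nulls

        stage = "diversity"
        div = diversity_table(counts, metadata, depth=cfg.depth, n_norm=cfg.n_norm,
                              seed=seeds["diversity"])
        results["diversity"] = div
        div_rows = []
        for trt in TREATMENTS:
            for index in ("rad_decay", "evenness", "richness"):
                try:
                    res = diversity_vs_dilution(div, trt, index)
                except (InsufficientDataError, KillWinnerError) as err:
                    log.info("diversity LMM skipped (%s, %s): %s", trt, index, err)
                    continue
                div_rows.append({"treatment": trt, "index": index,
                                 **dataclasses.asdict(res)})
        results["diversity_lmm"] = pd.DataFrame(div_rows)

        comp = composition_maintenance(counts, metadata, n_sub=cfg.n_sub,
                                       depth=cfg.depth, seed=seeds["composition"])
        results["composition_distance"] = comp["distances"]
        results["composition_regressions"] = comp["regressions"]
        results["ancova"] = pd.DataFrame([dataclasses.asdict(a) for a in comp["ancova"]])

        stage = "classification"
        cls = pd.concat(
            [classify_asvs(rates["fits"], cause, alpha=cfg.alpha) for cause in ("P", "PV")],
            ignore_index=True,
        )
        results["asv_classification"] = cls
        results["classification_counts"] = pd.concat(
            [classification_counts(cls[cls["cause"] == c]).assign(cause=c)
             for c in ("P", "PV")],
            ignore_index=True,
        )
        if taxonomy is None:
            taxonomy = pd.DataFrame({"taxon_id": counts.index, "order": "Unassigned"})
        results["order_summary"] = pd.concat(
            [order_summary(cls[cls["cause"] == c], taxonomy).assign(cause=c)
             for c in ("P", "PV")],
            ignore_index=True,
        )
    except KillWinnerError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    if out_dir is not None:
        write_results(results, out_dir)
    return results


def write_results(results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in OUTPUT_TABLES:
        key = name[: -len(".tsv")]
        df = results.get(key)
        if df is None:
            continue
        df.to_csv(out / name, sep="\t", index=False)
    for cause, null in results.get("permutation_nulls", {}).items():
        np.savetxt(out / f"permutation_null_{cause}.txt", null)
    cfg: PipelineConfig = results["config"]
    manifest = {
        "package": "killwinner",
        "version": __version__,
        "config": cfg.to_dict(),
        "record_counts": {
            k: int(len(v)) for k, v in results.items() if isinstance(v, pd.DataFrame)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
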