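"""End-to-end assessment pipeline and report bundle.

``run_pipeline`` chains the analysis stages in the survey's natural order —
descriptive statistics, individual indices, composites (with a without-Cd
sensitivity variant), local representative enrichment, clustering, PCA and
the between-zone comparison — and writes a machine-readable ``report.json``
plus per-stage CSVs and a ``run.log`` into the output directory.

A stage that raises is recorded with its name and the remaining stages are
marked skipped. Re-running on identical inputs and seed produces a
byte-identical ``report.json`` (timestamps only go to the log).

Conventions: descriptive statistics use sample skewness and *excess*
kurtosis (both with the standard small-sample adjustments, as in pandas).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rd_io
from .cluster import DEFAULT_SEED, kmedoids, select_k, stability, stability_label, standardize, validity
from .composites import (
    contamination_degree,
    cpi,
    modified_contamination_degree,
    nemerow,
    pli,
    sensitivity_without,
)
from .datamodel import ConcentrationMatrix, ReferenceSet, ValidationError
from .indices import contamination_factor, enrichment_factor, igeo, pollution_index
from .local import ef_local_report
from .pca import compare_zones, contributions, pca, select_components

__all__ = ["descriptive_statistics", "run_pipeline"]

logger = logging.getLogger(__name__)

_STATS = ("mean", "min", "max", "std", "skew", "kurtosis")


def descriptive_statistics(conc: ConcentrationMatrix) -> pd.DataFrame:
    """Per-zone mean/min/max/sd/skewness/excess-kurtosis for every metal."""
    blocks = []
    for zone in conc.zones:
        df = conc.zone_data(zone)
        block = pd.DataFrame(
            {
                "mean": df.mean(), "min": df.min(), "max": df.max(),
                "std": df.std(ddof=1), "skew": df.skew(), "kurtosis": df.kurt(),
            }
        ).T
        block.index = pd.MultiIndex.from_product([[zone], _STATS])
        blocks.append(block)
    return pd.concat(blocks)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        if isinstance(out.index, pd.MultiIndex):
            out.index = [" / ".join(map(str, t)) for t in out.index]
        return {str(k): _jsonable(v) for k, v in out.to_dict(orient="index").items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.to_dict().items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(
    conc_path: str | Path | None = None,
    config_path: str | Path | None = None,
    out_dir: str | Path = ".",
    *,
    conc: ConcentrationMatrix | None = None,
    ref: ReferenceSet | None = None,
    normalizers: Sequence[str] | None = None,
    m: int = 3,
    candidate_ks: Sequence[int] = (2, 3, 4, 5, 6),
    stability_resamples: int = 100,
    metal_subset: Sequence[str] | None = None,
    exclude_metal: str | None = "Cd",
    seed: int = DEFAULT_SEED,
) -> dict:
    """Run the full assessment and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("roaddust")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if conc is None:
            zone_map = rd_io.read_zone_map(config_path) if config_path else {}
            conc = rd_io.read_concentrations(conc_path, zone_map=zone_map)
        if ref is None:
            ref = rd_io.read_reference_config(config_path) if config_path else ReferenceSet()
        norms = list(normalizers) if normalizers else [
            n for n in ref.normalizer_candidates if n in conc.metals
        ]
        report: dict = {"seed": seed, "zones": conc.zones, "metals": conc.metals}
        state: dict = {}

        def _csv(name: str, df: pd.DataFrame) -> None:
            df.to_csv(out / f"{name}.csv")

        def stage_descriptive() -> dict:
            stats = descriptive_statistics(conc)
            _csv("descriptive_statistics", stats)
            return {"statistics": stats}

        def stage_individual() -> dict:
            section: dict = {}
            pi = pollution_index(conc, ref)
            state["pi"] = pi
            for name, tab in (("Igeo", igeo(conc, ref)), ("PI", pi)):
                _csv(f"index_{name}", tab.values)
                _csv(f"index_{name}_classes", tab.classes)
                section[name] = {"values": tab.values, "classes": tab.classes}
            state["ef"] = {}
            for norm in norms:
                tab = enrichment_factor(conc, ref, normalizer=norm)
                state["ef"][norm] = tab
                _csv(f"index_EF_{norm}", tab.values)
                section[f"EF_{norm}"] = {"values": tab.values, "classes": tab.classes}
            return section

        def stage_composites() -> dict:
            section: dict = {}
            pi = state["pi"]
            for op in (pli, nemerow, cpi):
                full, without = sensitivity_without(
                    op, pi, exclude_metal, metal_subset
                ) if exclude_metal and exclude_metal in pi.values.columns else (
                    op(pi, metal_subset), None)
                entry = {"values": full.values, "classes": full.classes}
                if without is not None:
                    entry[f"values_without_{exclude_metal}"] = without.values
                    entry[f"classes_without_{exclude_metal}"] = without.classes
                section[full.index_name] = entry
                _csv(f"composite_{full.index_name}", full.values.to_frame())
            cd_section: dict = {}
            for zone in conc.zones:
                try:
                    cf = contamination_factor(conc, ref, zone)
                except ValidationError as exc:
                    cd_section[zone] = {"notice": str(exc)}
                    continue
                cd = contamination_degree(cf)
                mcd = modified_contamination_degree(cf)
                cd_section[zone] = {
                    "CF": cf.values, "CF_classes": cf.classes,
                    "CD": cd.per_zone, "CD_class": cd.classes,
                    "mCD": mcd.per_zone, "mCD_class": mcd.classes,
                }
            section["degree_of_contamination"] = cd_section
            return section

        def stage_local() -> dict:
            section: dict = {}
            for zone in conc.zones:
                section[zone] = {}
                for norm in norms:
                    table = ef_local_report(conc, ref, zone, normalizer=norm, m=m)
                    _csv(f"ef_local_{zone}_{norm}", table)
                    section[zone][norm] = table
            return section

        def stage_cluster() -> dict:
            section: dict = {}
            for zone in conc.zones:
                Z = standardize(conc.zone_data(zone))
                n = Z.shape[0]
                ks = [k for k in candidate_ks if 2 <= k <= n - 1]
                if len(ks) < 2:
                    section[zone] = {"notice": f"zone {zone!r} has too few sites to cluster"}
                    continue
                sel = select_k(Z, ks, seed=seed)
                sol = kmedoids(Z, sel.chosen_k, seed=seed)
                scores = validity(sol, Z)
                jac = stability(Z, sel.chosen_k, B=stability_resamples, seed=seed)
                section[zone] = {
                    "candidate_ks": list(sel.candidate_ks),
                    "votes": sel.votes,
                    "chosen_k": sel.chosen_k,
                    "medoid_sites": sol.medoid_sites,
                    "assignment": sol.assignment,
                    "total_cost": sol.total_cost,
                    "validity": scores,
                    "stability": jac,
                    "stability_labels": {int(c): stability_label(v) for c, v in jac.items()},
                }
                _csv(f"clusters_{zone}", sol.assignment.to_frame())
            return section

        def stage_pca() -> dict:
            section: dict = {}
            for zone in conc.zones:
                res = pca(conc, zone)
                sel = select_components(res)
                dims = list(range(1, max(sel.chosen, 1) + 1))
                section[zone] = {
                    "eigenvalues": res.eigenvalues,
                    "explained_pct": res.explained_pct,
                    "cumulative_pct": res.cumulative_pct,
                    "kaiser_count": sel.kaiser_count,
                    "variance_count": sel.variance_count,
                    "chosen_components": sel.chosen,
                    "loadings": res.loadings,
                    "contributions_pct": res.contributions_pct,
                    "combined_contribution_pct": contributions(res, dims),
                    "expected_average_contribution": res.expected_average_contribution,
                }
                _csv(f"pca_loadings_{zone}", res.loadings)
            return section

        def stage_compare() -> dict:
            zones = conc.zones
            if len(zones) < 2:
                return {"notice": "need at least two zones to compare"}
            tables: dict = {}
            for name, builder in (
                ("Igeo", lambda z: _zone_table(igeo, z)),
                ("PI", lambda z: _zone_table(pollution_index, z)),
            ):
                tables[name] = {z: builder(z) for z in zones}
            for norm in norms:
                tables[f"EF_{norm}"] = {
                    z: enrichment_factor(_zone_conc(z), ref, normalizer=norm)
                    for z in zones
                }
            table = compare_zones(tables)
            _csv("zone_comparison", table)
            return {"kruskal_wallis": table}

        def _zone_conc(zone: str) -> ConcentrationMatrix:
            sites = conc.zone_sites(zone)
            return ConcentrationMatrix(conc.data.loc[sites],
                                       {s: zone for s in sites})

        def _zone_table(op, zone: str):
            return op(_zone_conc(zone), ref)

        stages = [
            ("descriptive_statistics", stage_descriptive),
            ("individual_indices", stage_individual),
            ("composite_indices", stage_composites),
            ("local_representative", stage_local),
            ("clustering", stage_cluster),
            ("pca", stage_pca),
            ("zone_comparison", stage_compare),
        ]
        failed: str | None = None
        for name, fn in stages:
            if failed is not None:
                report[name] = {"status": "skipped",
                                "reason": f"stage {failed!r} failed"}
                continue
            try:
                logger.info("running stage %s", name)
                report[name] = {"status": "ok", **_jsonable(fn())}
            except Exception as exc:  # noqa: BLE001 — reported, not hidden
                logger.exception("stage %s failed", name)
                report[name] = {"status": "error", "error": str(exc)}
                failed = name
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
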