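"""End-to-end orchestration: simulate -> growth fit -> indicators -> GRM ->
REML, with table/figure rendering and a reproducible run record.

The two ponds are analyzed as separate datasets joined only through the
genomic relationship matrix: univariate fits per trait per pond, bivariate
fits among traits within each pond, and cross-environment bivariate fits
(residual covariance fixed at zero) for the resilience indicators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .grm import compute_grm, write_grm
from .growthfit import estimate_weight_exponent, fit_individual_lines, heteroscedasticity_profile
from .indicators import descriptive_stats, resilience_table
from .records import PONDS, WeightRecordSet, write_dosages
from .simdata import SimConfig, simulate_genotypes, simulate_weights
from .varcomp import build_design, reml_bivariate, reml_univariate

log = logging.getLogger(__name__)

TRAITS = ("lnvar_ind", "lnvar_coh", "dgc", "w5")


@dataclass
class RunConfig:
    out_dir: str = "growvar_run"
    seed: int = 1
    sim: SimConfig | None = None
    records_csv: str | None = None  # alternative to simulation
    dosages_tsv: str | None = None
    dev_scale: str = "inv_f"
    cohort_floor: int = 5
    min_maf: float = 0.01
    grm_blend: float = 0.01
    traits: tuple[str, ...] = TRAITS
    within_pond_pairs: bool = True
    cross_env_traits: tuple[str, ...] = ("lnvar_ind", "lnvar_coh")
    make_figures: bool = True
    log_level: str = "INFO"


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write paper-style outputs under ``out_dir``.

    Emits: the simulated inputs (records CSV, dosage TSV, GRM), a Table-1
    style descriptive summary, a Table-2 style variance-component table,
    Table-3/4 style correlation matrices per pond, a cross-environment
    genetic-correlation table, deviation diagnostics (Fig 1-3 analogues),
    an EBV scatter (Fig 4 analogue) and a JSON run record.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if config.records_csv is None:
            sim = config.sim or SimConfig()
            ped, dosages = simulate_genotypes(sim, seed=config.seed)
            per_pond, truth = simulate_weights(sim, pedigree=ped, seed=config.seed + 1)
            records = WeightRecordSet(
                pd.concat([per_pond[p].data for p in PONDS], ignore_index=True)
            )
            records.to_csv(out / "weights.csv")
            write_dosages(out / "dosages.tsv", ped["fish_id"], dosages)
            truth.to_json(out / "sim_truth.json")
            geno_ids = ped["fish_id"].tolist()
        else:
            records = WeightRecordSet.from_csv(config.records_csv)
            from .records import read_dosages

            geno_ids, dosages = read_dosages(config.dosages_tsv)
        timings[stage] = time.time() - t0

        # ---- growth fit -------------------------------------------------
        stage = "growthfit"
        t0 = time.time()
        exp_fit = estimate_weight_exponent(records)
        fits = fit_individual_lines(records, exp_fit.f)
        het = heteroscedasticity_profile(fits)
        het.to_csv(out / "deviation_profile.csv", index=False)
        timings[stage] = time.time() - t0

        # ---- indicators -------------------------------------------------
        stage = "indicators"
        t0 = time.time()
        table = resilience_table(records, fits, cohort_floor=config.cohort_floor)
        table.to_csv(out / "resilience_table.csv")
        desc = descriptive_stats(table, traits=config.traits)
        desc.to_csv(out / "table1_descriptives.csv")
        timings[stage] = time.time() - t0

        # ---- GRM --------------------------------------------------------
        stage = "grm"
        t0 = time.time()
        grm = compute_grm(dosages, geno_ids, min_maf=config.min_maf, blend=config.grm_blend)
        write_grm(out / "grm.txt", grm)
        timings[stage] = time.time() - t0

        # ---- REML -------------------------------------------------------
        stage = "reml"
        t0 = time.time()
        comp_rows, corr_tables, ebv_frames = [], {}, {}
        for pond in PONDS:
            sub = table[table["pond"] == pond]
            for trait in config.traits:
                y, X, ids, _ = build_design(sub, trait, grm, covariate_sw=(trait == "w5"))
                res = reml_univariate(y, X, grm, ids, trait=trait)
                comp_rows.append(
                    {
                        "pond": pond,
                        "trait": trait,
                        "sigma2_a": res.sigma2_a[trait],
                        "sigma2_e": res.sigma2_e[trait],
                        "sigma2_p": res.sigma2_p[trait],
                        "h2": res.h2[trait],
                        "h2_se": res.h2_se[trait],
                        "converged": res.converged,
                    }
                )
            if config.within_pond_pairs:
                k = len(config.traits)
                rg = pd.DataFrame(np.nan, index=config.traits, columns=config.traits)
                rp = rg.copy()
                for i in range(k):
                    for j in range(i + 1, k):
                        ta, tb = config.traits[i], config.traits[j]
                        # restrict to fish carrying both traits before coding
                        # factors, so no level yields an empty design column
                        both = sub[sub[ta].notna() & sub[tb].notna()]
                        ya, Xa, ia, _ = build_design(both, ta, grm, covariate_sw=(ta == "w5"))
                        yb, Xb, ib, _ = build_design(both, tb, grm, covariate_sw=(tb == "w5"))
                        res = reml_bivariate(
                            ya, Xa, ia, yb, Xb, ib,
                            grm, residual_cov_free=True, traits=(ta, tb),
                        )
                        rg.loc[ta, tb] = rg.loc[tb, ta] = res.r_g
                        rp.loc[ta, tb] = rp.loc[tb, ta] = res.r_p
                corr_tables[pond] = {"genetic": rg, "phenotypic": rp}
                rg.to_csv(out / f"corr_genetic_{pond}.csv")
                rp.to_csv(out / f"corr_phenotypic_{pond}.csv")
        pd.DataFrame(comp_rows).to_csv(out / "table2_components.csv", index=False)

        cross_rows = []
        for trait in config.cross_env_traits:
            sub_a = table[table["pond"] == "aerated"]
            sub_n = table[table["pond"] == "non_aerated"]
            ya, Xa, ia, _ = build_design(sub_a, trait, grm)
            yn, Xn, _in, _ = build_design(sub_n, trait, grm)
            res = reml_bivariate(
                ya, Xa, ia, yn, Xn, _in, grm,
                residual_cov_free=False,
                traits=(f"{trait}_aerated", f"{trait}_non_aerated"),
            )
            ebv_frames[trait] = res.ebv
            cross_rows.append(
                {"trait": trait, "r_g": res.r_g, "r_g_se": res.r_g_se,
                 "converged": res.converged,
                 **{f"sigma2_a_{k}": v for k, v in res.sigma2_a.items()}}
            )
        cross = pd.DataFrame(cross_rows)
        cross.to_csv(out / "cross_environment_rg.csv", index=False)
        timings[stage] = time.time() - t0

        # ---- figures ----------------------------------------------------
        if config.make_figures:
            stage = "figures"
            t0 = time.time()
            _deviation_figures(het, out)
            _ebv_scatter(ebv_frames, cross, out)
            timings[stage] = time.time() - t0

        # ---- run record -------------------------------------------------
        record = {
            "growvar_version": __version__,
            "seed": config.seed,
            "weight_exponent_f": exp_fit.f,
            "config": {k: v for k, v in asdict(config).items() if k != "sim"},
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "input_hashes": {
                p.name: _sha1(p) for p in sorted(out.glob("*.csv"))
            },
            "total_s": round(time.time() - t_start, 3),
        }
        (out / "run_record.json").write_text(json.dumps(record, indent=2, default=str))
        return {
            "exponent": exp_fit,
            "resilience": table,
            "descriptives": desc,
            "components": pd.DataFrame(comp_rows),
            "correlations": corr_tables,
            "cross_environment": cross,
            "record": record,
        }
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(f"failed at stage: {stage}\n")
        log.exception("pipeline failed at stage %s", stage)
        raise


def _deviation_figures(het: pd.DataFrame, out: Path) -> None:
    for scale, sub in het.groupby("scale"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(sub["age"], sub["dev_mean"], yerr=sub["dev_sd"], fmt="o-", capsize=4)
        ax.axhline(0.0, color="grey", lw=0.8)
        unit = {"inv_f": "g$^{1/f}$", "observed": "g", "cubic": "g$^{1/3}$"}[scale]
        ax.set_xlabel("age (days)")
        ax.set_ylabel(f"deviation ({unit})")
        ax.set_title(f"deviations on the {scale} scale (mean $\\pm$ SD)")
        fig.tight_layout()
        fig.savefig(out / f"fig_deviations_{scale}.svg")
        plt.close(fig)


def _ebv_scatter(ebv_frames: dict, cross: pd.DataFrame, out: Path) -> None:
    if not ebv_frames:
        return
    fig, axes = plt.subplots(1, len(ebv_frames), figsize=(4.5 * len(ebv_frames), 4))
    axes = np.atleast_1d(axes)
    for ax, (trait, ebv) in zip(axes, ebv_frames.items()):
        cols = ebv.columns
        ax.scatter(ebv[cols[0]], ebv[cols[1]], s=6, alpha=0.5)
        row = cross.loc[cross["trait"] == trait].iloc[0]
        ax.set_xlabel(f"EBV {trait} (aerated)")
        ax.set_ylabel(f"EBV {trait} (non-aerated)")
        ax.set_title(f"$r_g$ = {row['r_g']:.2f} $\\pm$ {row['r_g_se']:.2f}")
    fig.tight_layout()
    fig.savefig(out / "fig_ebv_scatter.svg")
    plt.close(fig)
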