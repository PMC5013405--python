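"""Single-command orchestration of the full analysis grid.

For each configured outcome the pipeline runs: harmonization →
instrument-strength and frequency-concordance diagnostics → the four
estimators (IVW, MR-Egger, SIMEX-corrected MR-Egger, weighted median) on
all SNPs → influence classification → re-estimation on non-influential
SNPs → neuronal / non-neuronal subgroup estimates → heterogeneity and
random-effects meta-regression → forward selection of biological
moderators → leave-one-category-out and selected-category-exclusion
reruns.  Results land in one tab-delimited long table plus per-stage
reports and a machine-readable manifest; a single global seed derives
per-stage seeds by stage-name hashing so adding a stage never perturbs
earlier draws.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .diagnostics import heterogeneity, influence_tests
from .estimators import (MRResult, SimexConfig, ivw, mr_egger, ratio_estimates,
                         simex_egger, weighted_median)
from .meta_regression import forward_select, re_meta_regression
from .subgroups import (CategoryScheme, exclude_selected, leave_category_out,
                        split_neuronal)
from .summary_io import (DiagnosticUnavailable, ProxyMap, eaf_concordance,
                         harmonize, instrument_strength, read_association_table,
                         write_exclusions, write_harmonized)

logger = logging.getLogger("mrkit")

RESULT_COLUMNS = ("outcome", "snp_set", "method", "n_snps", "estimate_logor",
                  "se", "ci_low", "ci_high", "p", "or", "or_ci_low",
                  "or_ci_high", "intercept_odds", "intercept_ci_low",
                  "intercept_ci_high", "intercept_p", "i2_gx", "seed")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class OutcomeSpec:
    label: str
    path: str
    n_cases: float
    n_controls: float
    proxies: Optional[str] = None


@dataclass
class RunConfig:
    exposure: str
    outcomes: list[OutcomeSpec]
    outdir: str
    n_exposure: float = 322_154.0
    categories: Optional[str] = None
    delta_order: str = "second"          # SE order for heterogeneity / meta-regression
    tau2_estimator: str = "REML"
    simex_lambdas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    simex_reps: int = 1000
    n_boot: int = 1000
    min_category_size: int = 9
    forward_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.exposure).exists():
            raise FileNotFoundError(f"exposure table not found: {self.exposure}")
        labels = [o.label for o in self.outcomes]
        if len(labels) != len(set(labels)):
            raise ValueError("outcome labels must be unique")
        for o in self.outcomes:
            if not Path(o.path).exists():
                raise FileNotFoundError(f"outcome table not found: {o.path}")
            if o.proxies and not Path(o.proxies).exists():
                raise FileNotFoundError(f"proxy map not found: {o.proxies}")
        if self.categories and not Path(self.categories).exists():
            raise FileNotFoundError(f"category scheme not found: {self.categories}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
        if "simex_lambdas" in raw:
            raw["simex_lambdas"] = tuple(raw["simex_lambdas"])
        return cls(outcomes=outcomes, **raw)


def _result_row(outcome: str, snp_set: str, res: MRResult) -> dict:
    row = {
        "outcome": outcome, "snp_set": snp_set, "method": res.method,
        "n_snps": res.n_snps, "estimate_logor": res.estimate, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
        "or": res.or_, "or_ci_low": res.or_ci[0], "or_ci_high": res.or_ci[1],
        "intercept_odds": "", "intercept_ci_low": "", "intercept_ci_high": "",
        "intercept_p": "", "i2_gx": "", "seed": "" if res.seed is None else res.seed,
    }
    if res.intercept is not None:
        row["intercept_odds"] = res.intercept_odds
        row["intercept_ci_low"] = res.intercept_odds_ci[0]
        row["intercept_ci_high"] = res.intercept_odds_ci[1]
        row["intercept_p"] = res.intercept_p
    if res.i2_gx is not None:
        row["i2_gx"] = res.i2_gx
    return row


def _four_methods(instruments, simex_cfg: SimexConfig, n_boot: int, wm_seed: int):
    yield ivw(instruments)
    yield mr_egger(instruments)
    yield simex_egger(instruments, simex_cfg)
    yield weighted_median(instruments, n_boot=n_boot, seed=wm_seed)


def run(config: RunConfig) -> Path:
    """Execute the full grid; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "mrkit_version": __version__,
        "seed": config.seed,
        "settings": {
            "delta_order": config.delta_order,
            "tau2_estimator": config.tau2_estimator,
            "simex_lambdas": list(config.simex_lambdas),
            "simex_reps": config.simex_reps,
            "n_boot": config.n_boot,
            "min_category_size": config.min_category_size,
            "forward_alpha": config.forward_alpha,
            "residual_scale": "multiplicative (truncated below at 1)",
            "ci_quantile": "gaussian",
            "influence_df_convention": "stated",
            "multiple_testing": "none (raw p-values across the grid)",
        },
        "stage_seeds": {},
        "outcomes": {},
        "warnings": [],
    }

    exposure = read_association_table(config.exposure, "exposure")
    scheme_all = CategoryScheme.from_table(config.categories) \
        if config.categories else None

    results_rows: list[dict] = []
    for spec in config.outcomes:
        logger.info("=== outcome %s ===", spec.label)
        odir = outdir / spec.label
        odir.mkdir(exist_ok=True)
        ometa: dict = {}
        outcome_assocs = read_association_table(spec.path, "outcome")
        proxies = ProxyMap.from_table(spec.proxies) if spec.proxies else None
        harm = harmonize(exposure, outcome_assocs, proxies)
        write_harmonized(harm.instruments, odir / "harmonized.tsv")
        write_exclusions(harm.excluded, odir / "exclusions.tsv")
        manifest["warnings"].extend(f"{spec.label}: {w}" for w in harm.warnings)
        ometa["n_instruments"] = len(harm)
        ometa["n_excluded"] = len(harm.excluded)
        ometa["n_proxied"] = sum(1 for i in harm if i.proxy_of)

        strength = instrument_strength(
            harm.instruments, target_n=spec.n_cases + spec.n_controls,
            source_n=config.n_exposure)
        pd.DataFrame({
            "scope": ["exposure_gwas", "outcome_rescaled"],
            "mean_f": [strength.mean, strength.rescaled.mean],
            "sd_f": [strength.sd, strength.rescaled.sd],
            "median_f": [strength.median, strength.rescaled.median],
            "iqr_f": [strength.iqr, strength.rescaled.iqr],
        }).to_csv(odir / "strength.tsv", sep="\t", index=False, float_format="%.6g")
        try:
            conc = eaf_concordance(harm.instruments)
            ometa["eaf_concordance"] = conc.r
            ometa["eaf_concordance_n"] = conc.n_pairs
        except DiagnosticUnavailable as exc:
            manifest["warnings"].append(f"{spec.label}: {exc}")

        simex_cfg = SimexConfig(
            lambdas=config.simex_lambdas, reps_per_lambda=config.simex_reps,
            seed=stage_seed(config.seed, f"simex:{spec.label}"))
        wm_seed = stage_seed(config.seed, f"wm:{spec.label}")
        manifest["stage_seeds"][f"simex:{spec.label}"] = simex_cfg.seed
        manifest["stage_seeds"][f"wm:{spec.label}"] = wm_seed

        influence = influence_tests(harm.instruments)
        influence.table.to_csv(odir / "influence.tsv", sep="\t", index=False,
                               float_format="%.10g")
        flagged = influence.influential_snps
        ometa["influential_snps"] = sorted(flagged)
        noninfl = [i for i in harm if i.snp_id not in flagged]

        scheme = None
        if scheme_all is not None:
            scheme = CategoryScheme(
                members={c: set(s) for c, s in scheme_all.members.items()},
                neuronal_labels=scheme_all.neuronal_labels)

        snp_sets: list[tuple[str, list]] = [("all", list(harm)),
                                            ("non_influential", noninfl)]
        if scheme is not None:
            for tag, inst in [("all", list(harm)), ("non_influential", noninfl)]:
                neuronal, other = split_neuronal(inst, scheme)
                snp_sets.append((f"{tag}:neuronal", neuronal))
                snp_sets.append((f"{tag}:other", other))

        for set_name, inst in snp_sets:
            if len(inst) < 3:
                manifest["warnings"].append(
                    f"{spec.label}/{set_name}: only {len(inst)} SNPs; skipped")
                continue
            for res in _four_methods(inst, simex_cfg, config.n_boot, wm_seed):
                results_rows.append(_result_row(spec.label, set_name, res))

        ratios = ratio_estimates(harm.instruments, se_order=config.delta_order)
        het = heterogeneity(ratios, tau2_estimator=config.tau2_estimator)
        pd.DataFrame([{
            "Q": het.Q, "df": het.df, "q_p": het.q_p,
            "i2_higgins": het.i2_higgins, "tau2": het.tau2,
            "tau2_estimator": het.tau2_estimator, "i2_model": het.i2_model,
        }]).to_csv(odir / "heterogeneity.tsv", sep="\t", index=False,
                   float_format="%.10g")

        infl_indicator = pd.DataFrame({
            "influential": [int(i.snp_id in flagged) for i in harm]})
        mr_rows = []
        if infl_indicator["influential"].nunique() > 1:
            fit_infl = re_meta_regression(ratios, infl_indicator,
                                          tau2_estimator=config.tau2_estimator)
            mr_rows.append({"moderators": "influential", **_mr_fields(fit_infl)})
        else:
            fit_null = re_meta_regression(ratios, None,
                                          tau2_estimator=config.tau2_estimator)
            mr_rows.append({"moderators": "", **_mr_fields(fit_null)})
        if scheme is not None:
            neuro_snps: set[str] = set()
            for lab in scheme.neuronal_labels:
                neuro_snps |= scheme.members.get(lab, set())
            neuro_ind = pd.DataFrame({"neuronal": [
                int(i.snp_id in neuro_snps or (i.proxy_of in neuro_snps))
                for i in harm]})
            if neuro_ind["neuronal"].nunique() > 1:
                fit_neuro = re_meta_regression(ratios, neuro_ind,
                                               tau2_estimator=config.tau2_estimator)
                mr_rows.append({"moderators": "neuronal", **_mr_fields(fit_neuro)})
            else:
                manifest["warnings"].append(
                    f"{spec.label}: neuronal indicator is constant; "
                    "neuronal meta-regression skipped")
        pd.DataFrame(mr_rows).to_csv(odir / "meta_regression.tsv", sep="\t",
                                     index=False, float_format="%.10g")

        selected: list[str] = []
        if scheme is not None:
            big = scheme.restrict(config.min_category_size)
            if len(big.members) >= 2:
                indicators = big.indicator_frame(harm.instruments)
                sel = forward_select(ratios, indicators,
                                     alpha=config.forward_alpha,
                                     tau2_estimator=config.tau2_estimator)
                sel.trace.to_csv(odir / "forward_selection.tsv", sep="\t",
                                 index=False, float_format="%.10g")
                selected = sel.selected
                ometa["forward_selected"] = selected
                leave_category_out(harm.instruments, big).to_csv(
                    odir / "leave_one_out.tsv", sep="\t", index=False,
                    float_format="%.10g")
                exclude_selected(
                    harm.instruments, selected, big, simex_config=simex_cfg,
                    n_boot=config.n_boot, seed=wm_seed,
                ).to_csv(odir / "excluded_categories.tsv", sep="\t", index=False,
                         float_format="%.10g")
        manifest["outcomes"][spec.label] = ometa

    results = pd.DataFrame(results_rows, columns=list(RESULT_COLUMNS))
    results.to_csv(outdir / "results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return outdir


def _mr_fields(fit) -> dict:
    return {
        "tau2_null": fit.tau2_null, "tau2_residual": fit.tau2_residual,
        "adjusted_r2": fit.adjusted_r2, "residual_i2": fit.residual_i2,
        "qm_p": fit.qm_p, "qe_p": fit.qe_p,
        "tau2_estimator": fit.tau2_estimator,
    }
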