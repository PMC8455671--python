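"""Synthetic early-dynamic-biomarker cohorts with known ground truth.

Generates cohorts shaped like a ~47-patient early-response imaging/ctDNA
study: per-patient lesion tables at baseline and day 14, scan-level QC
metadata, variant-level plasma ctDNA calls at baseline / day 14 /
progression, and a clinical outcome table — all driven by a latent
"benefit" status per patient. Benefiting patients shrink their lesions'
SUVmax (mean multiplicative effect 0.74, i.e. a 26% mean decrease), clear
their ctDNA with high probability, and draw longer exponential
progression-free survival; non-benefiting patients keep their uptake, may
grow new lesions, retain ctDNA, and progress fast. Ground truth (latent
status, hazards, per-lesion effects, per-mutation clearance factors) is
returned alongside so every downstream estimator can be checked against
the generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ctdna as _ctdna
from . import io as _io
from . import pet as _pet
from . import survival as _survival

__all__ = ["CohortConfig", "Cohort", "RecoveryReport", "simulate_cohort", "recover_parameters"]

_GENE_WEIGHTS = {
    # marginal sampling weights among detected mutations; ESR1 and PIK3CA
    # dominate as the most frequently altered genes in this setting
    "ESR1": 0.30,
    "PIK3CA": 0.28,
    "TP53": 0.18,
    "AKT1": 0.08,
    "PTEN": 0.07,
    "ERBB2": 0.05,
    "FGFR1": 0.04,
}



def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))

@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults emulate the study conditions.

    Group sizes, detection rates, response effect sizes, survival medians
    and missingness track the emulated trial (47 patients, one missing
    baseline plasma, a handful of missing day-14 samples, baseline ctDNA
    detection ~56.5%, mean SUV decrease 26% in benefiting patients,
    group PFS medians 6.4 vs 2.2 months).
    """

    n_patients: int = 47
    seed: int = 0
    p_latent_benefit: float = 0.333

    # lesions
    lesion_count_extra_mean: float = 2.5  # n_lesions = 1 + Poisson(.), capped at 15
    suvmax_log_mean: float = math.log(6.0)
    suvmax_log_sd: float = 0.5
    response_effect_benefit: float = 0.74
    response_effect_nonbenefit: float = 1.0
    lesion_heterogeneity_sd: float = 0.10  # lognormal sigma of per-lesion noise
    p_new_lesion_nonbenefit: float = 0.25
    p_new_lesion_benefit: float = 0.0

    # ctDNA
    p_detect_baseline: float = 0.565
    p_second_mutation: float = 0.30  # never more than 2 mutations per patient
    copies_log_mean: float = math.log(50.0)
    copies_log_sd: float = 1.2
    p_clear_benefit: float = 0.70
    p_clear_nonbenefit: float = 0.10
    clearance_log_mean_benefit: float = math.log(0.05)
    clearance_log_mean_nonbenefit: float = math.log(0.8)
    clearance_log_sd: float = 0.8
    detection_floor_copies: float = 0.5  # below this a day-14 mutation reads as absent

    # outcome
    median_pfs_benefit_months: float = 6.4
    median_pfs_nonbenefit_months: float = 2.2
    censor_median_months: float = 40.0

    # missingness
    p_missing_baseline_plasma: float = 0.02
    p_missing_d14_plasma: float = 0.09
    p_progression_sample: float = 0.70

    def validate(self) -> None:
        probs = {
            "p_latent_benefit": self.p_latent_benefit,
            "p_new_lesion_nonbenefit": self.p_new_lesion_nonbenefit,
            "p_new_lesion_benefit": self.p_new_lesion_benefit,
            "p_detect_baseline": self.p_detect_baseline,
            "p_second_mutation": self.p_second_mutation,
            "p_clear_benefit": self.p_clear_benefit,
            "p_clear_nonbenefit": self.p_clear_nonbenefit,
            "p_missing_baseline_plasma": self.p_missing_baseline_plasma,
            "p_missing_d14_plasma": self.p_missing_d14_plasma,
            "p_progression_sample": self.p_progression_sample,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        for name in (
            "suvmax_log_sd",
            "lesion_heterogeneity_sd",
            "copies_log_sd",
            "clearance_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "median_pfs_benefit_months",
            "median_pfs_nonbenefit_months",
            "censor_median_months",
            "response_effect_benefit",
            "response_effect_nonbenefit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def generating_hr(self) -> float:
        """True hazard ratio of the benefit group vs the non-benefit group."""
        return self.median_pfs_nonbenefit_months / self.median_pfs_benefit_months


@dataclass
class Cohort:
    """Generated tables plus the ground truth that produced them."""

    lesions: pd.DataFrame
    scans: pd.DataFrame
    variants: pd.DataFrame
    clinical: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("lesions", "scans", "variants", "clinical", "samples", "truth"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


_ORGAN_CHOICES = ["liver", "lung", "bone", "node", "other"]
_ORGAN_PROBS = [0.30, 0.25, 0.20, 0.15, 0.10]
_CONSEQUENCES = ["missense", "nonsense", "frameshift", "splice"]
_CONSEQUENCE_PROBS = [0.80, 0.08, 0.08, 0.04]
_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw one cohort; deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given. Per-patient survival is
    exponential with rate ln 2 / group median; day-14 lesion SUVmax is
    baseline x group effect x lognormal lesion noise; day-14 mutated
    copies/ml are baseline x a per-mutation clearance factor (zero with the
    group's clearance probability).
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    lesion_rows, scan_rows, variant_rows, clinical_rows, sample_rows, truth_rows = (
        [],
        [],
        [],
        [],
        [],
        [],
    )
    genes = list(_GENE_WEIGHTS)
    gene_p = np.array(list(_GENE_WEIGHTS.values()))
    gene_p = gene_p / gene_p.sum()

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        benefit = bool(rng.random() < cfg.p_latent_benefit)
        effect = cfg.response_effect_benefit if benefit else cfg.response_effect_nonbenefit

        # --- reference uptake and scan metadata (shared scanner, matched QC)
        liver_mean = _clip(rng.normal(2.0, 0.2), 1.2, 3.0)
        liver_sd = _clip(rng.normal(0.25, 0.05), 0.05, 0.6)
        bp_mean = _clip(rng.normal(1.6, 0.15), 1.0, 2.5)
        bp_sd = _clip(rng.normal(0.2, 0.04), 0.05, 0.5)
        liver_abnormal = bool(rng.random() < 0.10)
        scanner = f"scanner{int(rng.integers(1, 6))}"
        activity = _clip(rng.normal(250.0, 25.0), 150.0, 370.0)
        threshold = (
            2.0 * (bp_mean + 2 * bp_sd) if liver_abnormal else 1.5 * (liver_mean + 2 * liver_sd)
        )

        for tp, days in (("baseline", int(rng.integers(-5, 0))), ("d14", 14)):
            scan_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "injected_activity_mbq": round(activity * float(rng.normal(1.0, 0.03)), 1),
                    "uptake_time_min": round(float(rng.uniform(60.0, 70.0)), 1),
                    "glucose_mg_dl": round(_clip(rng.normal(95.0, 15.0), 60.0, 190.0), 1),
                    "scanner_id": scanner,
                    "days_from_treatment_start": days,
                    "liver_suvmean": round(liver_mean, 3),
                    "liver_suvsd": round(liver_sd, 3),
                    "bloodpool_suvmean": round(bp_mean, 3),
                    "bloodpool_suvsd": round(bp_sd, 3),
                    "liver_abnormal": int(liver_abnormal),
                }
            )

        # --- lesions
        n_lesions = 1 + int(min(rng.poisson(cfg.lesion_count_extra_mean), 14))
        organs = rng.choice(_ORGAN_CHOICES, size=n_lesions, p=_ORGAN_PROBS)
        for j in range(n_lesions):
            lid = f"{pid}_L{j + 1:02d}"
            suvmax = float(rng.lognormal(cfg.suvmax_log_mean, cfg.suvmax_log_sd))
            if j == 0:
                suvmax = max(suvmax, threshold * 1.15)  # guarantee >=1 evaluable lesion
            peak_ratio = float(rng.uniform(0.80, 0.95))
            diameter = _clip(rng.lognormal(math.log(2.2), 0.4), 0.6, 12.0)
            matv = _clip(rng.lognormal(math.log(12.0), 0.8), 0.5, 400.0)
            noise = float(rng.lognormal(0.0, cfg.lesion_heterogeneity_sd))
            suvmax_d14 = suvmax * effect * noise
            base = {
                "patient_id": pid,
                "lesion_id": lid,
                "organ": organs[j],
                "diameter_cm": round(diameter, 2),
                "is_new": 0,
            }
            lesion_rows.append(
                base
                | {
                    "timepoint": "baseline",
                    "suvmax": round(suvmax, 3),
                    "suvpeak": round(suvmax * peak_ratio, 3),
                    "matv_cm3": round(matv, 2),
                }
            )
            lesion_rows.append(
                base
                | {
                    "timepoint": "d14",
                    "suvmax": round(suvmax_d14, 3),
                    "suvpeak": round(suvmax_d14 * peak_ratio, 3),
                    "matv_cm3": round(matv * (effect * noise) ** 1.5, 2),
                }
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "record": "lesion_effect",
                    "key": lid,
                    "value": effect * noise,
                }
            )

        p_new = cfg.p_new_lesion_benefit if benefit else cfg.p_new_lesion_nonbenefit
        new_lesion = bool(rng.random() < p_new)
        if new_lesion:
            suv_new = max(float(rng.lognormal(cfg.suvmax_log_mean, cfg.suvmax_log_sd)), threshold)
            lesion_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": f"{pid}_NEW",
                    "organ": str(rng.choice(_ORGAN_CHOICES)),
                    "timepoint": "d14",
                    "suvmax": round(suv_new, 3),
                    "suvpeak": round(suv_new * 0.9, 3),
                    "diameter_cm": round(float(rng.lognormal(math.log(1.5), 0.3)), 2),
                    "matv_cm3": round(float(rng.lognormal(math.log(4.0), 0.6)), 2),
                    "is_new": 1,
                }
            )

        # --- ctDNA
        base_plasma = rng.random() >= cfg.p_missing_baseline_plasma
        d14_plasma = rng.random() >= cfg.p_missing_d14_plasma
        prog_plasma = rng.random() < cfg.p_progression_sample
        sample_rows.extend(
            {"patient_id": pid, "timepoint": tp, "sample_present": int(present)}
            for tp, present in (
                ("baseline", base_plasma),
                ("d14", d14_plasma),
                ("progression", prog_plasma),
            )
        )

        detected = bool(rng.random() < cfg.p_detect_baseline)
        n_mut = 0
        if detected:
            n_mut = 1 + int(rng.random() < cfg.p_second_mutation)  # hard cap of 2
        p_clear = cfg.p_clear_benefit if benefit else cfg.p_clear_nonbenefit
        cl_mu = cfg.clearance_log_mean_benefit if benefit else cfg.clearance_log_mean_nonbenefit
        mut_genes = rng.choice(genes, size=n_mut, replace=False, p=gene_p) if n_mut else []
        for g in mut_genes:
            prot = f"p.{_AA[rng.integers(len(_AA))]}{int(rng.integers(30, 999))}{_AA[rng.integers(len(_AA))]}"
            copies = float(rng.lognormal(cfg.copies_log_mean, cfg.copies_log_sd))
            vaf = _clip(rng.lognormal(math.log(8.0), 1.0), 0.05, 80.0)
            cleared = bool(rng.random() < p_clear)
            factor = 0.0 if cleared else float(rng.lognormal(cl_mu, cfg.clearance_log_sd))
            regrow = float(rng.lognormal(math.log(1.5), 0.6))
            consequence = str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_PROBS))
            classification = "pathogenic" if rng.random() < 0.8 else "vus"
            truth_rows.append(
                {"patient_id": pid, "record": "clearance_factor", "key": g, "value": factor}
            )

            def _row(tp: str, c: float, v: float) -> dict:
                v = min(max(v, 0.0), 95.0)
                total = c / max(v / 100.0, 1e-4) if c > 0 else float(
                    rng.lognormal(math.log(800.0), 0.5)
                )
                return {
                    "patient_id": pid,
                    "timepoint": tp,
                    "gene": g,
                    "protein_change": prot,
                    "consequence": consequence,
                    "classification": classification,
                    "vaf_pct": round(v, 3),
                    "mut_copies_per_ml": round(c, 3),
                    "total_copies_per_ml": round(total, 1),
                    "coverage": int(rng.integers(1000, 20000)),
                    "fwd_fraction": round(float(rng.uniform(0.35, 0.65)), 3),
                }

            if base_plasma:
                variant_rows.append(_row("baseline", copies, vaf))
            c14 = copies * factor
            if d14_plasma and c14 >= cfg.detection_floor_copies:
                variant_rows.append(_row("d14", c14, vaf * factor))
            cprog = copies * regrow
            if prog_plasma and cprog >= cfg.detection_floor_copies:
                variant_rows.append(_row("progression", cprog, min(vaf * regrow, 95.0)))

        # --- outcome and covariates
        median = cfg.median_pfs_benefit_months if benefit else cfg.median_pfs_nonbenefit_months
        hazard = math.log(2.0) / median
        t_event = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.exponential(cfg.censor_median_months / math.log(2.0)))
        pfs = round(min(t_event, t_censor), 2)
        event = int(t_event <= t_censor)
        clinical_rows.append(
            {
                "patient_id": pid,
                "pfs_months": pfs,
                "event": event,
                "age_years": int(_clip(rng.normal(57.0, 11.0), 35, 85)),
                "ecog": int(rng.choice([0, 1, 2], p=[0.49, 0.49, 0.02])),
                "n_sites": int(1 + rng.poisson(1.2)),
                "visceral": int(rng.random() < 0.74),
                "prior_ct_lines": int(rng.poisson(0.9)),
                "prior_et_lines": int(1 + rng.poisson(1.0)),
                "nsai_sensitive": int(rng.random() < 0.70),
                "prior_cdk46": int(rng.random() < 0.26),
            }
        )
        truth_rows.extend(
            [
                {"patient_id": pid, "record": "latent_benefit", "key": "", "value": float(benefit)},
                {"patient_id": pid, "record": "hazard", "key": "", "value": hazard},
                {"patient_id": pid, "record": "new_lesion", "key": "", "value": float(new_lesion)},
            ]
        )

    cohort = Cohort(
        lesions=pd.DataFrame(lesion_rows, columns=_io.LESION_COLUMNS),
        scans=pd.DataFrame(scan_rows, columns=_io.SCAN_COLUMNS),
        variants=pd.DataFrame(variant_rows, columns=_io.VARIANT_COLUMNS),
        clinical=pd.DataFrame(clinical_rows, columns=_io.CLINICAL_COLUMNS),
        samples=pd.DataFrame(sample_rows, columns=_io.SAMPLE_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=["patient_id", "record", "key", "value"]),
        config=cfg,
    )
    return cohort


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline estimates on a simulated cohort next to the generating truth."""

    generating_hr: float
    hr_latent_benefit: float
    hr_consist15: float
    hr_consist25: float
    km_median_benefit: float
    km_median_nonbenefit: float
    detection_rate_baseline_pct: float
    detection_rate_d14_pct: float
    configured_detection_baseline_pct: float
    median_cdr: float
    n_patients: int


def recover_parameters(cohort: Cohort) -> RecoveryReport:
    """Run the full pipeline on a simulated cohort and compare to truth.

    Classifies metabolic response at the 25% and 15% cut-offs from the
    generated lesion/scan tables, builds ctDNA statuses from the variant
    table, and estimates Cox hazard ratios (responder vs non-responder, and
    latent benefit vs not) plus Kaplan-Meier medians per latent group.
    """
    pairs = _io.build_scan_pairs(cohort.lesions, cohort.scans)
    responder: dict[float, dict[str, bool]] = {15.0: {}, 25.0: {}}
    for pair in pairs:
        for cutoff in (15.0, 25.0):
            responder[cutoff][pair.patient_id] = _pet.classify_consist(
                pair, cutoff_pct=cutoff
            ).responder

    statuses = _io.build_ctdna_statuses(cohort.variants, cohort.samples)
    det_base = _ctdna.detection_rate(statuses, "baseline")
    det_d14 = _ctdna.detection_rate(statuses, "d14")
    cdrs = [s.cdr for s in statuses if s.cdr is not None]

    clin = cohort.clinical.set_index("patient_id")
    benefit = (
        cohort.truth.query("record == 'latent_benefit'")
        .set_index("patient_id")["value"]
        .astype(bool)
    )

    def hr_for(flags: dict[str, bool]) -> float:
        sub = clin.loc[list(flags)]
        x = np.array([float(flags[p]) for p in sub.index])
        if np.unique(x).size < 2:
            return float("nan")
        return _survival.cox_univariate(sub["pfs_months"], sub["event"], x).hr

    hr_latent = hr_for({p: bool(benefit.loc[p]) for p in clin.index})
    b_mask = benefit.reindex(clin.index).to_numpy()
    km_b = _survival.km_median(clin.loc[b_mask, "pfs_months"], clin.loc[b_mask, "event"])
    km_nb = _survival.km_median(clin.loc[~b_mask, "pfs_months"], clin.loc[~b_mask, "event"])

    return RecoveryReport(
        generating_hr=cohort.config.generating_hr,
        hr_latent_benefit=hr_latent,
        hr_consist15=hr_for(responder[15.0]),
        hr_consist25=hr_for(responder[25.0]),
        km_median_benefit=km_b,
        km_median_nonbenefit=km_nb,
        detection_rate_baseline_pct=det_base.pct,
        detection_rate_d14_pct=det_d14.pct,
        configured_detection_baseline_pct=100.0 * cohort.config.p_detect_baseline,
        median_cdr=float(np.median(cdrs)) if cdrs else float("nan"),
        n_patients=cohort.config.n_patients,
    )
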