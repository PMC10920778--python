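"""End-to-end orchestration of the habitat analysis over a cohort.

Stages: quadrant (p-q) segmentation per subject; mixture (ND-ODI)
segmentation with cohort-level class matching; cognition association
battery; BOLD global-signal coupling with habitat comparison; and spatial
similarity between the two segmentations. Each stage is a plain function
over in-memory cohort objects so it can run on generated or loaded data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cognition as cg
from . import coupling as cp
from .diffusion import contralateral_reference, normalize_and_extract
from .gmm import (
    PartitionMatchTable, match_partitions, remove_outliers, select_k, to_subregions,
)
from .grids import binarize_probabilistic_mask, mirror_contralateral_mask, read_volume, MaskVolume
from .pq import SubregionSet, assign_quadrants
from .similarity import cross_scheme_table
from .synthetic import Cohort, SubjectData, SyntheticCohortSpec

logger = logging.getLogger(__name__)

__all__ = [
    "segment_pq_subject",
    "segment_pq_cohort",
    "segment_gmm_cohort",
    "cognition_analysis",
    "coupling_analysis",
    "similarity_analysis",
    "run_pipeline",
    "load_cohort",
]


def _contra_mask(subject: SubjectData) -> MaskVolume:
    return mirror_contralateral_mask(subject.tumour_mask)


def segment_pq_subject(subject: SubjectData) -> SubregionSet:
    """Normalize p and q by the contralateral means and label quadrants."""
    contra = _contra_mask(subject)
    ref_p = contralateral_reference(subject.p_map, contra)
    ref_q = contralateral_reference(subject.q_map, contra)
    sample = normalize_and_extract(
        subject.p_map, subject.q_map, subject.tumour_mask, ref_p, ref_q,
        feature_names=("p", "q"),
    )
    return assign_quadrants(sample, tumour=subject.tumour_mask)


def segment_pq_cohort(cohort: Cohort) -> tuple[dict[str, SubregionSet], pd.DataFrame]:
    """Quadrant subregions for every subject plus the occupancy table."""
    sets, rows = {}, []
    for s in cohort.subjects:
        sub = segment_pq_subject(s)
        sets[s.subject] = sub
        rows.append({"subject": s.subject, **{f"occ_{g}": sub.occupancy[g]
                                              for g in sub.names}})
    return sets, pd.DataFrame(rows).set_index("subject")


def segment_gmm_cohort(
    cohort: Cohort, seed: int = 0, tau: float = 0.3
) -> tuple[dict[str, SubregionSet], PartitionMatchTable, pd.DataFrame, pd.DataFrame]:
    """Mixture segmentation of the ND-ODI plane with cross-subject matching.

    Returns per-subject subregion sets, the match table, the per-subject
    occupancy/presence table, and a per-class cohort summary (mean feature
    values of member centroids, % of subjects carrying the class, mean
    occupancy when present).
    """
    fits, samples = {}, {}
    for i, s in enumerate(cohort.subjects):
        contra = _contra_mask(s)
        ref_nd = contralateral_reference(s.nd_map, contra)
        ref_odi = contralateral_reference(s.odi_map, contra)
        sample = normalize_and_extract(
            s.nd_map, s.odi_map, s.tumour_mask, ref_nd, ref_odi,
            feature_names=("ND", "ODI"),
        )
        filtered = remove_outliers(sample)
        _, fit, _ = select_k(filtered, seed=seed + 1000 * i)
        fits[s.subject] = fit
        samples[s.subject] = filtered
    match = match_partitions(fits, tau=tau)
    sets, rows = {}, []
    for s in cohort.subjects:
        sub = to_subregions(
            fits[s.subject], samples[s.subject],
            match.assignment_for(s.subject), match.class_names, s.tumour_mask,
        )
        sets[s.subject] = sub
        row = {"subject": s.subject}
        for c in match.class_names:
            row[f"occ_{c}"] = sub.occupancy[c]
            row[f"present_{c}"] = sub.presence[c]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject")
    summary_rows = []
    for c in match.class_names:
        members = match.table[match.table["class"] == c]
        cents = np.array([
            fits[r.subject].means[r.component] for r in members.itertuples()
        ])
        present_occ = table.loc[table[f"present_{c}"], f"occ_{c}"]
        summary_rows.append({
            "class": c,
            "mean_f1": cents[:, 0].mean(), "sd_f1": cents[:, 0].std(ddof=1),
            "mean_f2": cents[:, 1].mean(), "sd_f2": cents[:, 1].std(ddof=1),
            "pct_patients": 100.0 * len(members) / len(cohort.subjects),
            "mean_occ_when_present": present_occ.mean(),
            "sd_occ_when_present": present_occ.std(ddof=1),
        })
    return sets, match, table, pd.DataFrame(summary_rows).set_index("class")


def cognition_analysis(
    cohort: Cohort,
    pq_occupancy: pd.DataFrame,
    noddi_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, object]:
    """The full association battery between habitats and cognitive change."""
    man = cohort.manifest.set_index("subject")
    changes = {}
    for sub, row in man.iterrows():
        pre = {d: row[f"pre_{d}"] for d in cg.DOMAINS}
        post = {d: row[f"post_{d}"] for d in cg.DOMAINS}
        changes[sub] = cg.compute_change(pre, post)
    complete = [s for s, c in changes.items() if not c.excluded]
    logger.info("cognition analyses on %d/%d participants", len(complete), len(man))
    change = np.array([changes[s].mean_overall for s in complete])
    volume = man.loc[complete, "tumour_volume_cm3"].to_numpy()

    # occupancy regressions, one per quadrant group, FDR over the family
    groups = [c.removeprefix("occ_") for c in pq_occupancy.columns]
    reports = {}
    for g in groups:
        occ = pq_occupancy.loc[complete, f"occ_{g}"].to_numpy()
        reports[g] = cg.occupancy_regression(change, occ, volume)
    adj = cg.bh_fdr([reports[g].p_model for g in groups])
    for g, p in zip(groups, adj):
        reports[g].p_fdr = float(p)

    # per-domain follow-ups where the overall model survives FDR
    domain_changes = pd.DataFrame(
        {d: [changes[s].delta[d] for s in complete] for d in cg.DOMAINS}
    )
    followups = {}
    for g in groups:
        if reports[g].p_fdr < alpha:
            occ = pq_occupancy.loc[complete, f"occ_{g}"].to_numpy()
            followups[g] = cg.domain_followup_regressions(domain_changes, occ, volume)

    # presence comparisons for the data-driven classes, FDR over the family
    presence_reports = {}
    if noddi_table is not None:
        classes = [c.removeprefix("present_") for c in noddi_table.columns
                   if c.startswith("present_")]
        tested = []
        for c in classes:
            pres = noddi_table.loc[complete, f"present_{c}"].to_numpy(bool)
            if pres.all() or (~pres).all():
                logger.info("class %s present in all or no subjects: skipped", c)
                continue
            presence_reports[c] = cg.presence_comparison(change, pres)
            tested.append(c)
        adj = cg.bh_fdr([presence_reports[c].p for c in tested])
        for c, p in zip(tested, adj):
            presence_reports[c].p_fdr = float(p)

    # IDH association for each quadrant group's occupancy
    idh = man.loc[complete, "idh_mutated"].to_numpy(bool)
    idh_occ = {}
    for g in groups:
        occ = pq_occupancy.loc[complete, f"occ_{g}"].to_numpy()
        z, p = cg._mannwhitney_z(occ[idh], occ[~idh])
        idh_occ[g] = {"z": z, "p": p}

    screen = cg.covariate_screen(
        man.loc[complete, ["years_education", "age", "tumour_volume_cm3",
                           "tumour_volume_post_cm3", "grade",
                           "hippocampus_vol_pre", "hippocampus_act_pre"]],
        change,
    )
    return {
        "changes": changes,
        "complete_subjects": complete,
        "occupancy_regressions": reports,
        "domain_followups": followups,
        "presence_comparisons": presence_reports,
        "idh_occupancy_tests": idh_occ,
        "covariate_screen": screen,
    }


def coupling_analysis(
    cohort: Cohort, scheme_sets: dict[str, SubregionSet], standardized: bool = True
) -> dict[str, object]:
    """Per-subject coupling of each habitat (and contralateral) with the GS."""
    spec = cohort.spec
    estimates: list[cp.CouplingEstimate] = []
    keys: list[tuple[str, str]] = []
    for s in cohort.subjects:
        if s.bold is None:
            raise ValueError(f"{s.subject}: no BOLD series")
        sub = scheme_sets[s.subject]
        contra = _contra_mask(s)
        retained = None
        if s.fd is not None:
            retained, flagged = cp.scrub_frames(s.fd)
            if flagged:
                logger.warning("%s flagged for motion", s.subject)
        gs = cp.global_signal(s.bold, s.gm_mask, s.tumour_mask)
        gs_contra = cp.global_signal(s.bold, s.gm_mask, s.tumour_mask,
                                     also_exclude=contra)
        gs = cp.band_filter(gs, tr=spec.tr)
        gs_contra = cp.band_filter(gs_contra, tr=spec.tr)
        if retained is not None:
            gs, gs_contra = gs[retained], gs_contra[retained]
        for name in sub.names:
            mask = sub.masks[name]
            if mask.n_voxels == 0:
                continue
            ts = cp.band_filter(s.bold.data[mask.data].mean(axis=0), tr=spec.tr)
            if retained is not None:
                ts = ts[retained]
            estimates.append(cp.coupling_beta(ts, gs, region=name,
                                              standardized=standardized))
            keys.append((s.subject, name))
        ts = cp.band_filter(s.bold.data[contra.data].mean(axis=0), tr=spec.tr)
        if retained is not None:
            ts = ts[retained]
        estimates.append(cp.coupling_beta(ts, gs_contra, region="contralateral",
                                          standardized=standardized))
        keys.append((s.subject, "contralateral"))
    cp.zero_nonsignificant(estimates)
    beta = pd.DataFrame(
        [{"subject": k[0], "region": k[1], "beta": e.beta, "raw_beta": e.raw_beta,
          "p": e.p, "p_fdr": e.p_fdr, "zeroed": e.zeroed}
         for k, e in zip(keys, estimates)]
    )
    wide = beta.pivot(index="subject", columns="region", values="beta")
    scheme = next(iter(scheme_sets.values()))
    cols = [n for n in scheme.names if n in wide.columns] + ["contralateral"]
    wide = wide[cols]
    comparison = None
    if not wide.isna().any().any():
        comparison = cp.compare_coupling(wide)
    else:
        logger.info("incomplete habitat coverage: Friedman comparison skipped")
    return {"estimates": beta, "beta_table": wide, "comparison": comparison}


def similarity_analysis(
    pq_sets: dict[str, SubregionSet], noddi_sets: dict[str, SubregionSet]
) -> pd.DataFrame:
    """Cohort mean/SD Dice and both %Occ directions per subregion pair."""
    frames = []
    for sub in pq_sets:
        t = cross_scheme_table(pq_sets[sub], noddi_sets[sub])
        if len(t):
            t.insert(0, "subject", sub)
            frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["pq_group", "class", "dice_mean", "dice_sd",
                     "occ_in_group_mean", "occ_in_group_sd",
                     "occ_in_class_mean", "occ_in_class_sd", "n_subjects"]
        )
    allpairs = pd.concat(frames, ignore_index=True)
    agg = (
        allpairs.groupby(["pq_group", "class"])
        .agg(
            dice_mean=("dice", "mean"), dice_sd=("dice", "std"),
            occ_in_group_mean=("occ_of_pair_in_pq_group", "mean"),
            occ_in_group_sd=("occ_of_pair_in_pq_group", "std"),
            occ_in_class_mean=("occ_of_pair_in_class", "mean"),
            occ_in_class_sd=("occ_of_pair_in_class", "std"),
            n_subjects=("subject", "count"),
        )
        .reset_index()
    )
    return agg


def run_pipeline(cohort: Cohort, seed: int = 0, with_bold: bool = True) -> dict:
    """Run every stage on a cohort and collect the result tables."""
    pq_sets, pq_occ = segment_pq_cohort(cohort)
    noddi_sets, match, noddi_table, noddi_summary = segment_gmm_cohort(cohort, seed=seed)
    cog = cognition_analysis(cohort, pq_occ, noddi_table)
    coup = None
    if with_bold and cohort.subjects[0].bold is not None:
        coup = coupling_analysis(cohort, pq_sets)
    sim = similarity_analysis(pq_sets, noddi_sets)
    return {
        "pq_sets": pq_sets,
        "pq_occupancy": pq_occ,
        "noddi_sets": noddi_sets,
        "match": match,
        "noddi_table": noddi_table,
        "noddi_summary": noddi_summary,
        "cognition": cog,
        "coupling": coup,
        "similarity": sim,
    }


def load_cohort(data_dir: str | Path) -> Cohort:
    """Load a cohort written by ``generate_cohort`` (or arranged likewise)."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    spec_file = data_dir / "cohort_spec.yaml"
    spec = SyntheticCohortSpec()
    if spec_file.exists():
        import yaml

        from .synthetic import HabitatClass

        raw = yaml.safe_load(spec_file.read_text())
        raw["pq_classes"] = [HabitatClass(**c) for c in raw["pq_classes"]]
        raw["noddi_classes"] = [HabitatClass(**c) for c in raw["noddi_classes"]]
        for key in ("grid_shape", "tumour_size_range", "ref_scale", "gs_band"):
            raw[key] = tuple(raw[key])
        raw["noddi_shared_cov"] = tuple(tuple(r) for r in raw["noddi_shared_cov"])
        spec = SyntheticCohortSpec(**raw)
    subjects = []
    for _, row in manifest.iterrows():
        sd = data_dir / row["subject"]
        tumour_prob = read_volume(sd / "tumour_prob.nii.gz")
        tumour = binarize_probabilistic_mask(tumour_prob, 0.5)
        gm_vol = read_volume(sd / "gm_mask.nii.gz")
        bold_file = sd / "bold.nii.gz"
        subjects.append(
            SubjectData(
                subject=row["subject"],
                tumour_prob=tumour_prob,
                tumour_mask=tumour,
                contra_mask=mirror_contralateral_mask(tumour),
                gm_mask=MaskVolume(data=gm_vol.data > 0.5, affine=gm_vol.affine),
                p_map=read_volume(sd / "p.nii.gz"),
                q_map=read_volume(sd / "q.nii.gz"),
                nd_map=read_volume(sd / "nd.nii.gz"),
                odi_map=read_volume(sd / "odi.nii.gz"),
                bold=read_volume(bold_file) if bold_file.exists() else None,
                fd=None,
                record=row.to_dict(),
                truth=None,
            )
        )
    return Cohort(spec=spec, subjects=subjects, manifest=manifest)
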