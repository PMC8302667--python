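"""File-level plumbing shared by the CLI: readers/writers, model dispatch,
and the end-to-end run (simulate -> build -> fit -> score -> evaluate ->
assoc) driven by a config mapping."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import auprc, auroc, bin_prevalence, spearman_with_staging
from .features import (
    PresenceMatrix,
    build_presence_matrix,
    read_occurrences,
    split_cohort,
    standardize,
    utilization,
)
from .genetics import fit_null_model, gene_combined_test, read_vcf_blocks
from .genetics.vcf import read_gene_intervals
from .scores import (
    LPCModel,
    PheNormModel,
    PheRSModel,
    fit_lpc,
    fit_phenorm,
    fit_phers,
    score_lpc,
    score_phenorm,
    score_phers,
)
from .synthetic import CohortSpec, simulate_cohort, simulate_genotypes, write_vcf

MODEL_KINDS = {"phers": PheRSModel, "lpc": LPCModel, "phenorm": PheNormModel}


def load_model(path):
    with open(path) as fh:
        obj = json.load(fh)
    kind = obj.get("kind")
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    return MODEL_KINDS[kind].from_json(obj)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("subject_id").iloc[:, 0].astype(str)


def read_series(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.to_numeric(df.set_index("subject_id").iloc[:, 0])


def read_presence(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PresenceMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_series(s: pd.Series, path, name=None) -> None:
    s.rename(name or s.name or "value").rename_axis("subject_id").to_frame().to_csv(
        path, sep="\t"
    )


def _case_counts(p: PresenceMatrix, case_phecodes) -> np.ndarray:
    cols = [f for f in case_phecodes if f in p.features]
    if not cols:
        raise ValueError("none of the case-defining phecodes are in the matrix")
    idx = [p.features.index(f) for f in cols]
    return p.values[:, idx].sum(axis=1)


def fit_model(
    method: str,
    presence: PresenceMatrix,
    labels: pd.Series,
    case_phecodes=None,
    util: pd.Series | None = None,
    seed: int = 0,
    tw_alpha: float = 0.05,
    dropout: float = 0.3,
    bootstrap: int = 100_000,
    alpha_grid=None,
):
    """Fit one score model on a training presence matrix.

    PheRS and LPC exclude the case-defining phecodes from the feature set;
    PheNorm uses them only through the per-subject count.
    """
    case_phecodes = list(case_phecodes or [])
    other = [f for f in presence.features if f not in set(case_phecodes)]
    if method == "phers":
        reference = [s for s in presence.subjects if labels.get(s) == "control"]
        return fit_phers(presence.subset_features(other), reference)
    if method == "lpc":
        x = standardize(presence.subset_features(other))
        return fit_lpc(x, labels, alpha=tw_alpha)
    if method == "phenorm":
        if util is None:
            raise ValueError("PheNorm requires a utilization vector")
        if not case_phecodes:
            raise ValueError("PheNorm requires case-defining phecodes")
        x = standardize(presence.subset_features(other))
        counts = _case_counts(presence, case_phecodes)
        u = util.reindex(presence.subjects, fill_value=0).to_numpy()
        return fit_phenorm(
            x, counts, u, r=dropout, B=bootstrap, seed=seed, alpha_grid=alpha_grid
        )
    raise ValueError(f"unknown method {method!r}")


def score_model(
    model,
    presence: PresenceMatrix,
    case_phecodes=None,
    util: pd.Series | None = None,
) -> pd.Series:
    """Apply a fitted model to (new) subjects in a presence matrix."""
    if isinstance(model, PheRSModel):
        return score_phers(model, presence)
    if isinstance(model, LPCModel):
        x = standardize(presence.subset_features(model.features), stats=model.stats())
        return score_lpc(model, x)
    if isinstance(model, PheNormModel):
        if util is None or not case_phecodes:
            raise ValueError("PheNorm scoring needs utilization and case-defining phecodes")
        x = standardize(
            presence.subset_features(model.candidate_features), stats=model.stats()
        )
        counts = _case_counts(presence, case_phecodes)
        u = util.reindex(presence.subjects, fill_value=0).to_numpy()
        return score_phenorm(model, x, counts, u)
    raise TypeError(f"unknown model type {type(model).__name__}")


def evaluate_scores(
    scores: pd.Series,
    labels: pd.Series,
    staging: pd.Series | None = None,
    n_bins: int = 60,
    include_unknown_as_control: bool = False,
) -> dict:
    report = {
        "n_scored": int(len(scores)),
        "auroc": auroc(scores, labels),
        "auprc": auprc(scores, labels),
    }
    if staging is not None:
        rho, p = spearman_with_staging(scores, staging)
        report["spearman_rho"] = rho
        report["spearman_p"] = p
    n_eval = labels.loc[labels.astype(str).isin(["case", "control"])].index.intersection(
        scores.index
    )
    if len(n_eval) >= n_bins:
        tab = bin_prevalence(
            scores, labels, n_bins=n_bins,
            include_unknown_as_control=include_unknown_as_control,
        )
        report["bin_prevalence"] = tab.to_dict(orient="records")
    return report


def run_association(
    vcf_path,
    genes_path,
    scores: pd.Series,
    covariates: pd.DataFrame | None,
    family: str = "inverse-gaussian",
) -> pd.DataFrame:
    blocks = read_vcf_blocks(vcf_path, gene_intervals=read_gene_intervals(genes_path))
    null = fit_null_model(scores, covariates, family=family)
    keep = null.subjects
    rows = []
    for gene, block in sorted(blocks.items()):
        idx = [block.subjects.index(s) for s in keep]
        sub_block_dos = block.dosages[idx]
        # re-wrap with the analysis cohort only
        from .genetics.blocks import GenotypeBlock

        sub = GenotypeBlock(gene, keep, sub_block_dos, block.variants)
        rows.append(gene_combined_test(null, sub).to_row())
    return pd.DataFrame(rows)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir: Path, inputs: dict, seeds: dict, outputs: list) -> None:
    manifest = {
        "qrs_version": __version__,
        "python": platform.python_version(),
        "seeds": seeds,
        "inputs": {k: _checksum(v) for k, v in inputs.items() if Path(v).exists()},
        "outputs": [str(o) for o in outputs],
    }
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def simulate_to_dir(spec: CohortSpec, out_dir, seed: int | None = None) -> dict:
    """Emit a full synthetic dataset (occurrences, labels, staging,
    covariates, VCF) into ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, labels, staging, util, liability = simulate_cohort(spec, seed=seed)
    blocks, increment = simulate_genotypes(spec, seed=seed)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 2)
    subjects = labels.index
    covariates = pd.DataFrame(
        {
            "age": np.round(rng.uniform(30, 80, len(subjects)), 1),
            "sex": rng.integers(0, 2, len(subjects)),
            **{f"PC{k}": rng.standard_normal(len(subjects)) for k in range(1, 11)},
        },
        index=subjects,
    )
    files = {
        "occurrences": out / "occurrences.tsv",
        "labels": out / "labels.tsv",
        "staging": out / "staging.tsv",
        "utilization": out / "utilization.tsv",
        "covariates": out / "covariates.tsv",
        "vcf": out / "genotypes.vcf",
        "genes": out / "genes.bed",
    }
    records.rename(columns={"age_at_observation": "age"}).to_csv(
        files["occurrences"], sep="\t", index=False
    )
    write_series(labels, files["labels"], "label")
    write_series(staging, files["staging"], "stage")
    write_series(util, files["utilization"], "utilization")
    covariates.rename_axis("subject_id").to_csv(files["covariates"], sep="\t")
    write_vcf(blocks, files["vcf"])
    with open(files["genes"], "w") as fh:
        for gene, block in blocks.items():
            lo = min(v.pos for v in block.variants) - 1
            hi = max(v.pos for v in block.variants)
            fh.write(f"1\t{lo}\t{hi}\t{gene}\n")
    return {k: str(v) for k, v in files.items()}


def run(config: dict, out_dir) -> dict:
    """Full pipeline from a config mapping; returns a summary dict.

    Config keys (all optional, sensible defaults): ``spec`` (CohortSpec
    fields), ``seed``, ``method`` (phers|lpc|phenorm), ``min_occurrences``,
    ``case_fraction``, ``n_bins``, ``family``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    spec = CohortSpec(**{**config.get("spec", {}), "seed": seed})
    method = config.get("method", "lpc")
    files = simulate_to_dir(spec, out / "sim", seed=seed)

    records = read_occurrences(files["occurrences"])
    labels = read_labels(files["labels"])
    staging = read_series(files["staging"])
    roster = list(labels.index)
    presence = build_presence_matrix(
        records,
        min_occurrences=int(config.get("min_occurrences", 2)),
        roster=roster,
        features=spec.relevant_phecodes + spec.noise_phecodes,
    )
    util = utilization(records, roster=roster)
    train_ids, test_ids = split_cohort(labels, float(config.get("case_fraction", 0.5)), seed)

    model = fit_model(
        method,
        presence.subset_subjects(train_ids),
        labels,
        case_phecodes=spec.case_defining_phecodes,
        util=util,
        seed=seed,
        bootstrap=int(config.get("bootstrap", 20_000)),
        alpha_grid=config.get("alpha_grid"),
    )
    model_path = out / "model.json"
    model.save(model_path)

    test_scores = score_model(
        model,
        presence.subset_subjects(test_ids),
        case_phecodes=spec.case_defining_phecodes,
        util=util,
    )
    scores_path = out / "scores.tsv"
    write_series(test_scores, scores_path, "score")

    report = evaluate_scores(
        test_scores, labels, staging, n_bins=int(config.get("n_bins", 60))
    )
    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=1)

    covariates = pd.read_csv(files["covariates"], sep="\t", index_col="subject_id")
    all_scores = score_model(
        model, presence, case_phecodes=spec.case_defining_phecodes, util=util
    )
    assoc = run_association(
        files["vcf"],
        files["genes"],
        all_scores,
        covariates,
        family=config.get("family", "inverse-gaussian"),
    )
    assoc_path = out / "association.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)

    write_manifest(
        out,
        inputs=files,
        seeds={"seed": seed},
        outputs=[model_path, scores_path, out / "evaluation.json", assoc_path],
    )
    return {
        "files": files,
        "model": str(model_path),
        "scores": str(scores_path),
        "evaluation": report,
        "association": str(assoc_path),
    }
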