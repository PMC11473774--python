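"""CLI entry points and the leave-one-cohort-out evaluation harness."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import click
import numpy as np
import pandas as pd
import yaml

from .activation import (
    DeconvolvedCohort,
    call_activity,
    read_cohort_dir,
    write_cohort_dir,
    write_profile,
)
from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase, load_database, write_database
from .iris import IrisConfig, IrisEnsemble, train_iris
from .scoring import (
    auc_rank,
    confusion_counts,
    cv_of_aucs,
    enrichment_fisher,
    odds_ratio,
    score_samples,
    select_cutpoint,
)
from .social import SocialConfig, make_pseudo_samples, read_single_cell_dir, social_permutation_test
from .special import (
    SpecialConfig,
    infer_region_activity,
    read_spatial_dir,
    region_count_kmeans,
    segment_kmeans,
    segment_sliding_window,
)
from .synthetic import (
    CohortSimConfig,
    SingleCellSimConfig,
    SpatialSimConfig,
    simulate_cohorts,
    simulate_single_cell,
    simulate_spatial,
)


@dataclass
class LocoReport:
    """Per-held-out-cohort evaluation rows plus summary statistics."""

    rows: pd.DataFrame  # cohort_id, auc, odds_ratio, threshold, n_samples
    mean_auc: float
    cv: float
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows.to_dict("records"),
            "mean_auc": self.mean_auc,
            "cv": self.cv,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_loco(
    cohorts: Sequence[DeconvolvedCohort],
    db: InteractionDatabase,
    direction: str,
    config: IrisConfig,
) -> LocoReport:
    """Leave-one-cohort-out: train on the rest, score and evaluate the held-out cohort.

    Per fold, the ensemble is trained on the training cohorts only; the
    cut-point threshold is the mean of the per-training-cohort optima; AUC and
    odds ratio are measured on the held-out cohort's pre-treatment samples.
    """
    if len(cohorts) < 3:
        raise PreconditionError("run_loco requires at least three cohorts")
    rows = []
    provenance: dict[str, list[str]] = {}
    for held_out in cohorts:
        training = [c for c in cohorts if c.cohort_id != held_out.cohort_id]
        provenance[held_out.cohort_id] = [c.cohort_id for c in training]
        ensemble = train_iris(training, db, direction, config)

        train_scores = []
        train_ids = []
        for c in training:
            profile = call_activity(c, db, "pre")
            labels = (profile.samples["response"] == "R").to_numpy()
            if labels.all() or not labels.any():
                continue
            train_scores.append((score_samples(profile, ensemble), labels))
            train_ids.append(c.cohort_id)
        cut = select_cutpoint(train_scores, cohort_ids=train_ids)

        profile = call_activity(held_out, db, "pre")
        labels = (profile.samples["response"] == "R").to_numpy()
        scores = score_samples(profile, ensemble)
        auc = auc_rank(scores.raw.to_numpy(), labels)
        conf = confusion_counts(scores.scaled.to_numpy(), labels, cut.threshold)
        rows.append(
            {
                "cohort_id": held_out.cohort_id,
                "auc": auc,
                "odds_ratio": odds_ratio(conf),
                "threshold": cut.threshold,
                "n_samples": int(labels.size),
                "n_sets": len(ensemble.sets),
            }
        )
    frame = pd.DataFrame(rows)
    aucs = frame["auc"].to_numpy()
    return LocoReport(
        rows=frame,
        mean_auc=float(aucs.mean()),
        cv=cv_of_aucs(aucs) if len(aucs) >= 2 and aucs.mean() != 0 else float("nan"),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# CLI


def _load_iris_config(path: str | None, seed: int | None) -> IrisConfig:
    params = {}
    if path:
        params = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        params["random_seed"] = seed
    return IrisConfig(**params)


def _load_cohorts(cohorts_dir: str) -> list[DeconvolvedCohort]:
    root = Path(cohorts_dir)
    dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not dirs:
        raise ValidationError(f"{cohorts_dir}: no cohort subdirectories")
    return [read_cohort_dir(p) for p in dirs]


@click.group()
def cli() -> None:
    """Ligand-receptor interaction inference and immunotherapy-response scoring."""


@cli.group()
def simulate() -> None:
    """Generate synthetic datasets with planted signal."""


@simulate.command("cohorts")
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--n-cohorts", type=int, default=4)
def simulate_cohorts_cmd(seed: int, out_dir: str, n_cohorts: int) -> None:
    cfg = CohortSimConfig(n_cohorts=n_cohorts, random_seed=seed)
    cohorts, truth, db = simulate_cohorts(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in cohorts:
        write_cohort_dir(c, out / c.cohort_id)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    write_database(db, out / "database.tsv")
    click.echo(f"wrote {len(cohorts)} cohorts to {out}")


@simulate.command("sc")
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate_sc_cmd(seed: int, out_dir: str) -> None:
    from .social import write_single_cell_dir

    dataset, truth, db = simulate_single_cell(SingleCellSimConfig(random_seed=seed))
    out = Path(out_dir)
    write_single_cell_dir(dataset, out)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    write_database(db, out / "database.tsv")
    click.echo(f"wrote single-cell dataset ({dataset.n_cells} cells) to {out}")


@simulate.command("spatial")
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate_spatial_cmd(seed: int, out_dir: str) -> None:
    from .special import write_spatial_dir

    dataset, truth, db = simulate_spatial(SpatialSimConfig(random_seed=seed))
    out = Path(out_dir)
    write_spatial_dir(dataset, out)
    truth.rename_axis("cell_id").reset_index().to_csv(
        out / "ground_truth.tsv", sep="\t", index=False
    )
    write_database(db, out / "database.tsv")
    click.echo(f"wrote spatial dataset ({dataset.n_cells} cells) to {out}")


@cli.command()
@click.option("--cohort-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--timepoint", type=click.Choice(["pre", "post"]), default="pre")
@click.option("--out", "out_prefix", type=click.Path(), required=True)
def binarize(cohort_dir: str, db_path: str, timepoint: str, out_prefix: str) -> None:
    """Binarize interaction activity for one cohort directory."""
    db = load_database(db_path)
    cohort = read_cohort_dir(cohort_dir)
    profile = call_activity(cohort, db, timepoint)
    write_profile(profile, out_prefix)
    click.echo(f"wrote activity profile {out_prefix}.tsv")


@cli.command()
@click.option("--cohorts-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--direction", type=click.Choice(["rdi", "rui"]), default="rdi")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def train(cohorts_dir, db_path, direction, config_path, seed, out_path) -> None:
    """Train the two-step ensemble on a directory of cohort subdirectories."""
    db = load_database(db_path)
    cohorts = _load_cohorts(cohorts_dir)
    config = _load_iris_config(config_path, seed)
    ensemble = train_iris(cohorts, db, direction.upper(), config)
    ensemble.to_json(out_path)
    click.echo(f"wrote ensemble with {len(ensemble.sets)} sets to {out_path}")


@cli.command()
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--cohort-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--timepoint", type=click.Choice(["pre", "post"]), default="pre")
@click.option("--out", "out_path", type=click.Path(), required=True)
def score(model_path, cohort_dir, db_path, timepoint, out_path) -> None:
    """Score a cohort with a trained ensemble (per-sample raw/scaled TSV)."""
    db = load_database(db_path)
    ensemble = IrisEnsemble.from_json(model_path)
    cohort = read_cohort_dir(cohort_dir)
    profile = call_activity(cohort, db, timepoint)
    vec = score_samples(profile, ensemble)
    vec.to_frame().rename_axis("sample_id").to_csv(out_path, sep="\t")
    click.echo(f"wrote scores to {out_path}")


@cli.command()
@click.option("--scores", "scores_path", type=click.Path(exists=True), required=True)
@click.option("--cohort-dir", type=click.Path(exists=True), required=True)
@click.option("--threshold", type=float, default=0.0)
@click.option("--out", "out_path", type=click.Path(), required=True)
def evaluate(scores_path, cohort_dir, threshold, out_path) -> None:
    """AUC / odds-ratio report for scored samples against cohort response labels."""
    scores = pd.read_csv(scores_path, sep="\t", index_col="sample_id")
    cohort = read_cohort_dir(cohort_dir)
    common = [s for s in scores.index if s in cohort.samples.index]
    labels = (cohort.samples.loc[common, "response"] == "R").to_numpy()
    raw = scores.loc[common, "raw"].to_numpy()
    scaled = scores.loc[common, "scaled"].to_numpy()
    conf = confusion_counts(scaled, labels, threshold)
    report = {
        "n_samples": len(common),
        "auc": auc_rank(raw, labels),
        "threshold": threshold,
        "odds_ratio": odds_ratio(conf),
        "confusion": conf.tolist(),
    }
    Path(out_path).write_text(json.dumps(report, indent=1))
    click.echo(json.dumps(report))


@cli.command()
@click.option("--cohorts-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--direction", type=click.Choice(["rdi", "rui"]), default="rdi")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def loco(cohorts_dir, db_path, direction, config_path, seed, out_path) -> None:
    """Leave-one-cohort-out evaluation across cohort subdirectories."""
    db = load_database(db_path)
    cohorts = _load_cohorts(cohorts_dir)
    config = _load_iris_config(config_path, seed)
    report = run_loco(cohorts, db, direction.upper(), config)
    report.to_json(out_path)
    click.echo(f"mean held-out AUC {report.mean_auc:.3f} (CV {report.cv:.1f}%)")


@cli.command("social")
@click.option("--sc-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--pseudo/--no-pseudo", default=False, help="build down-sampled pseudo-samples per group")
@click.option("--out", "out_path", type=click.Path(), required=True)
def social_cmd(sc_dir, db_path, seed, pseudo, out_path) -> None:
    """Permutation-based interaction inference on single-cell data."""
    db = load_database(db_path)
    dataset = read_single_cell_dir(sc_dir)
    config = SocialConfig(random_seed=seed)
    if pseudo:
        samples = make_pseudo_samples(dataset, config)
    else:
        samples = [dataset if dataset.sample_id else
                   type(dataset)(dataset.expression, dataset.cell_type, dataset.group, "sample_0")]
    rng = np.random.default_rng(seed)
    frames = []
    for ds in samples:
        res = social_permutation_test(ds, db, config, rng=rng)
        res = res.reset_index()
        res.insert(0, "sample_id", ds.sample_id)
        frames.append(res)
    pd.concat(frames).to_csv(out_path, sep="\t", index=False)
    click.echo(f"wrote {len(samples)} sample result(s) to {out_path}")


@cli.command("special")
@click.option("--spatial-dir", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option("--mode", type=click.Choice(["kmeans", "sliding_window"]), default="kmeans")
@click.option("--n-regions", type=int, default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_prefix", type=click.Path(), required=True)
def special_cmd(spatial_dir, db_path, mode, n_regions, seed, out_prefix) -> None:
    """Segment a slide into regions and infer per-region interaction activity."""
    db = load_database(db_path)
    dataset = read_spatial_dir(spatial_dir)
    config = SpecialConfig(mode=mode, random_seed=seed)
    if mode == "kmeans":
        regions = segment_kmeans(dataset, config, n_regions=n_regions)
    else:
        regions = segment_sliding_window(dataset, config)
    result = infer_region_activity(dataset, regions, db, config)
    result.activity.rename_axis("interaction_id").to_csv(f"{out_prefix}.activity.tsv", sep="\t", na_rep="NA")
    summary = pd.DataFrame(
        {
            "count": result.counts,
            "count_scaled": result.counts_scaled,
        }
    )
    summary = summary.join(result.cell_type_fractions)
    summary.rename_axis("region_id").to_csv(f"{out_prefix}.regions.tsv", sep="\t")
    click.echo(f"wrote {len(regions)} regions to {out_prefix}.regions.tsv")


@cli.command("enrich")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--db", "db_path", type=click.Path(exists=True), required=True)
@click.option(
    "--grouping", type=click.Choice(["ligand_ct", "receptor_ct", "annotation"]), default="ligand_ct"
)
@click.option("--out", "out_path", type=click.Path(), required=True)
def enrich_cmd(model_path, db_path, grouping, out_path) -> None:
    """One-sided Fisher enrichment of the ensemble union against the database."""
    db = load_database(db_path)
    ensemble = IrisEnsemble.from_json(model_path)
    union = sorted({i for s in ensemble.sets for i in s.interaction_ids})
    table = enrichment_fisher(union, db, grouping)
    table.to_csv(out_path, sep="\t", index=False)
    click.echo(f"wrote enrichment table to {out_path}")


def main() -> int:
    try:
        cli.main(standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return 2
    except click.exceptions.Abort:
        return 1
    except ValidationError as exc:
        click.echo(f"validation error: {exc}", err=True)
        return 2
    except PreconditionError as exc:
        click.echo(f"precondition error: {exc}", err=True)
        return 3
    return 0


if __name__ == "__main__":
    sys.exit(main())
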