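"""End-to-end analysis pipeline.

Stages, in order: ingest TPS specimens (mirroring left-side curves),
resample to the semi-landmark template, within-species GPA and species
means, global GPA with necklace sliding, spiral metrics, ordinations (PCA,
Phy-PCA, PACA), phylogenetic signal (K per component, Kmult), the PGLS
battery with FDR-adjusted p-values, per-trait evolutionary model selection
with rate-shift search, and ancestral state reconstruction. Everything is
deterministic given the configuration and master seed; each stochastic
stage consumes an independent child seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evo_models, ordination, phylo_stats, shape_core, spiral_metrics
from .io_formats import (
    LandmarkConfiguration,
    Phylogeny,
    TraitTable,
    read_newick,
    read_tps,
    read_traits,
    write_tps,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("spiralshape")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    tps_dir: str
    tree_file: str
    traits_file: str
    out_dir: str
    seed: int
    specimen_map_file: str | None = None  # CSV: specimen_id,species_id[,side]
    n_semilandmarks: int = 67
    slide_max_outer: int = 10
    slide_tol: float = 1e-6
    n_perm: int = 999
    models: tuple = ("BM", "EB", "OU", "lambda", "kappa", "delta")
    max_shifts: int = 10
    n_components_signal: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("run configuration must set an explicit seed")
        return cls(**raw)


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(config: RunConfig) -> list[LandmarkConfiguration]:
    tps_dir = Path(config.tps_dir)
    if not tps_dir.exists():
        raise FileNotFoundError(f"TPS directory {tps_dir} does not exist")
    files = sorted(tps_dir.glob("*.tps"))
    if not files:
        raise FileNotFoundError(f"no .tps files in {tps_dir}")
    configs: list[LandmarkConfiguration] = []
    for f in files:
        configs.extend(read_tps(f))
    if config.specimen_map_file:
        from dataclasses import replace

        sidecar = pd.read_csv(config.specimen_map_file).set_index("specimen_id")
        mapped = []
        for c in configs:
            if c.specimen_id not in sidecar.index:
                raise KeyError(f"specimen {c.specimen_id} missing from sidecar")
            row = sidecar.loc[c.specimen_id]
            mapped.append(replace(
                c, species_id=str(row["species_id"]),
                side=str(row.get("side", c.side)),
            ))
        configs = mapped
    # left-side specimens are mirrored so all curves share chirality
    return [shape_core.mirror(c) if c.side == "left" else c for c in configs]


@_stage("tree")
def _load_tree(config: RunConfig) -> Phylogeny:
    return read_newick(config.tree_file)


@_stage("traits")
def _load_traits(config: RunConfig, tree: Phylogeny) -> TraitTable:
    return read_traits(config.traits_file, tree=tree)


@_stage("superimposition")
def _superimpose(configs, config: RunConfig):
    resampled = [
        shape_core.resample_equidistant(c, m=config.n_semilandmarks)
        for c in configs
    ]
    # within-species GPA then species means, then global GPA of the means
    by_species: dict[str, list] = {}
    for c in resampled:
        by_species.setdefault(c.species_id, []).append(c)
    species_configs = []
    for sp, members in sorted(by_species.items()):
        if len(members) == 1:
            species_configs.append(members[0])
        else:
            aligned = shape_core.gpa(members)
            pts = np.mean([m.points for m in aligned.configurations], axis=0)
            proto = members[0]
            # mean shape keeps the first member's curve for sliding
            species_configs.append(proto.with_points(
                pts * (np.linalg.norm(proto.points) / max(np.linalg.norm(pts), 1e-300))
            ))
    sample = shape_core.gpa(species_configs)
    slid, states = shape_core.necklace_slide(
        sample, max_outer=config.slide_max_outer, tol=config.slide_tol,
    )
    return resampled, slid, states


@_stage("metrics")
def _metrics(configs) -> pd.DataFrame:
    """Spiral metrics from the full-resolution digitized curves.

    The 70-landmark template is fine for shape analysis, but turn counting
    needs the densest sampling available: equidistant arc-length spacing
    leaves few points per radian on the innermost windings of strongly
    tapered curves.
    """
    rows = []
    for c in configs:
        m = spiral_metrics.count_turns(c)
        rows.append({
            "specimen_id": c.specimen_id,
            "species_id": c.species_id,
            "centroid_size": m.centroid_size,
            "cochlear_length": m.cochlear_length,
            "n_turns": m.n_turns,
        })
    df = pd.DataFrame(rows)
    return df.groupby("species_id", as_index=False).agg(
        centroid_size=("centroid_size", "mean"),
        cochlear_length=("cochlear_length", "mean"),
        n_turns=("n_turns", "mean"),
    )


@_stage("ordination")
def _ordinate(slid, tree):
    return {
        "pca": ordination.pca(slid),
        "phy_pca": ordination.phy_pca(slid, tree),
        "paca": ordination.paca(slid, tree),
    }


@_stage("signal")
def _signal(slid, ords, tree, config: RunConfig, seeds):
    res = {}
    kmult = phylo_stats.k_mult(slid, tree, n_perm=config.n_perm, seed=seeds[0])
    res["Kmult"] = {"value": kmult.value, "p": kmult.p_value}
    pca_ = ords["pca"]
    labels = pca_.labels
    for j in range(min(config.n_components_signal, pca_.scores.shape[1])):
        k = phylo_stats.blomberg_k(
            pca_.scores[:, j], tree, labels=labels,
            n_perm=config.n_perm, seed=seeds[1 + j],
        )
        res[f"K_PC{j + 1}"] = {"value": k.value, "p": k.p_value}
    return res


@_stage("pgls")
def _pgls_battery(slid, ords, metrics: pd.DataFrame, traits: TraitTable,
                  tree, config: RunConfig, seeds):
    merged = metrics.set_index("species_id")
    table = traits.data.join(merged, how="inner", lsuffix="", rsuffix="_m")
    table = table.loc[[s for s in tree.tip_labels if s in table.index]]
    if len(table) != tree.tip_count:
        missing = set(tree.tip_labels) - set(table.index)
        raise ValueError(f"species missing traits/metrics: {sorted(missing)}")
    labels = list(table.index)
    mass = np.log(table["body_mass"].to_numpy(float))
    length = table["cochlear_length"].to_numpy(float)
    turns = table["n_turns"].to_numpy(float)
    cs = table["centroid_size"].to_numpy(float)
    n = len(labels)

    rows = []
    pca_ = ords["pca"]
    pc_by_label = {lab: pca_.scores[i, :] for i, lab in enumerate(pca_.labels)}
    pcs = np.array([pc_by_label[lab] for lab in labels])

    def one(y, name, x, xname):
        X = np.column_stack([np.ones(n), x])
        fit = phylo_stats.pgls(y, X, tree, labels=labels)
        rows.append({
            "model": f"{name} ~ {xname}", "slope": fit.coefficients[1],
            "lambda": fit.lambda_, "r_squared": fit.r_squared,
            "p": fit.p_values[1],
        })

    for j in range(min(3, pcs.shape[1])):
        for x, xname in [(mass, "log_mass"), (cs, "centroid_size"),
                         (length, "length"), (turns, "n_turns")]:
            one(pcs[:, j], f"PC{j + 1}", x, xname)

    # multivariate shape regressions with the weighted-average lambda
    mv = {}
    for x, xname in [(mass, "log_mass"), (cs, "centroid_size"),
                     (length, "length"), (turns, "n_turns")]:
        X = np.column_stack([np.ones(n), x])
        res = phylo_stats.weighted_lambda_pgls(
            pcs, X, tree, labels=labels, n_perm=config.n_perm, seed=seeds[0],
        )
        mv[f"shape ~ {xname}"] = {
            "lambda_bar": res["lambda_bar"], "r_squared": res["r_squared"],
            "p": res["p_value"],
        }

    inter = phylo_stats.interaction_pgls(turns, mass, length, tree, labels=labels)
    interaction = {
        "coefficients": inter.coefficients.tolist(),
        "lambda": inter.lambda_, "r_squared": inter.r_squared,
        "p_interaction": float(inter.p_values[3]),
        "fitted": dict(zip(labels, inter.fitted.tolist())),
    }

    df = pd.DataFrame(rows)
    df["p_fdr"] = phylo_stats.fdr_adjust(df["p"].to_numpy())
    return df, mv, interaction, labels, turns, pcs


@_stage("evolution")
def _evolution(pcs, turns, labels, tree, config: RunConfig):
    traits = {f"PC{j + 1}": pcs[:, j] for j in range(min(3, pcs.shape[1]))}
    traits["n_turns"] = turns
    out = {}
    for name, y in traits.items():
        fits = []
        for model in config.models:
            if model in ("kappa", "delta") and not tree.is_ultrametric():
                logger.warning("skipping %s on non-ultrametric tree", model)
                continue
            try:
                fits.append(evo_models.fit_model(y, tree, model, labels=labels))
            except ValueError as exc:
                logger.warning("model %s failed for %s: %s", model, name, exc)
        best, ranked = evo_models.select_model(fits)
        base_params = {}
        if best.shape_name is not None:
            base_params[best.shape_name] = best.shape_param
        if best.model in ("BM", "EB", "kappa"):
            shifted_tree = evo_models.transform_tree(tree, best.model, base_params)
        else:
            shifted_tree = tree  # lambda/OU/delta act on the covariance
        shifts = evo_models.rate_shift_search(
            y, shifted_tree, max_shifts=config.max_shifts, labels=labels,
        )
        recon = evo_models.asr(y, shifts.tree, labels=labels)
        out[name] = {"fits": ranked, "best": best, "shifts": shifts,
                     "asr": recon}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes CSV/JSON outputs plus a manifest.

    Returns a dictionary with the in-memory results of every stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 8)

    configs = _ingest(config)
    tree = _load_tree(config)
    traits = _load_traits(config, tree)
    resampled, slid, states = _superimpose(configs, config)
    metrics = _metrics(configs)
    ords = _ordinate(slid, tree)
    signal = _signal(slid, ords, tree, config, seeds)
    pgls_df, mv, interaction, labels, turns, pcs = _pgls_battery(
        slid, ords, metrics, traits, tree, config, seeds)
    evolution = _evolution(pcs, turns, labels, tree, config)

    # ---- outputs ----
    manifest = {"config": asdict(config), "outputs": []}

    def emit_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    write_tps(slid.configurations, out_dir / "aligned.tps")
    manifest["outputs"].append("aligned.tps")
    emit_csv(metrics, "metrics.csv")

    pca_ = ords["pca"]
    scores = pd.DataFrame(
        pca_.scores[:, :10],
        columns=[f"PC{j + 1}" for j in range(pca_.scores[:, :10].shape[1])],
    )
    scores.insert(0, "species_id", pca_.labels)
    emit_csv(scores, "pca_scores.csv")
    emit_csv(pd.DataFrame({
        "component": np.arange(1, len(pca_.percent_explained) + 1),
        "percent_explained": pca_.percent_explained,
    }), "pca_variance.csv")

    emit_csv(pgls_df, "pgls.csv")
    with open(out_dir / "signal.json", "w") as fh:
        json.dump(signal, fh, indent=2)
    manifest["outputs"].append("signal.json")
    with open(out_dir / "multivariate_pgls.json", "w") as fh:
        json.dump(mv, fh, indent=2)
    manifest["outputs"].append("multivariate_pgls.json")
    with open(out_dir / "interaction.json", "w") as fh:
        json.dump(interaction, fh, indent=2)
    manifest["outputs"].append("interaction.json")

    model_rows = []
    shift_rows = []
    asr_rows = []
    for name, res in evolution.items():
        for f in res["fits"]:
            model_rows.append({
                "trait": name, "model": f.model, "sigma2": f.sigma2,
                "shape_param": f.shape_param, "logL": f.log_likelihood,
                "AICc": f.aicc,
                "selected": f.model == res["best"].model,
            })
        for s in res["shifts"].shifts:
            shift_rows.append({
                "trait": name, "node": s.node, "scope": s.scope,
                "multiplier": s.multiplier,
                "tips": ";".join(s.tip_labels),
            })
        rec = res["asr"]
        for node in range(len(rec.estimates)):
            asr_rows.append({
                "trait": name, "node_id": node,
                "estimate": rec.estimates[node],
                "variance": rec.variances[node],
                "is_tip": bool(rec.is_tip[node]),
                "label": rec.labels[node] or "",
            })
    emit_csv(pd.DataFrame(model_rows), "model_selection.csv")
    emit_csv(pd.DataFrame(shift_rows, columns=[
        "trait", "node", "scope", "multiplier", "tips"]), "rate_shifts.csv")
    emit_csv(pd.DataFrame(asr_rows), "asr.csv")

    with open(out_dir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "metrics": metrics, "ordinations": ords, "signal": signal,
        "pgls": pgls_df, "multivariate": mv, "interaction": interaction,
        "evolution": evolution, "aligned": slid, "tree": tree,
    }
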