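"""End-to-end orchestration: normalize → intrinsic → classes → signatures →
counterparts → pathways, with a manifest recording config, seeds, and
output hashes.

Each stage writes its products under the run directory and can be resumed
from them; the manifest's content digest covers the stage output hashes
(not wall-clock timestamps), so two runs with the same seed and inputs
agree on it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bundle import ExpressionBundle, GeneSetCollection
from .classes import UNASSIGNED, call_classes, classify_homogeneity
from .cluster import extract_groups, hcluster
from .config import PipelineConfig
from .cross_species import (collapse_orthologs, counterpart_gsa,
                            merge_species, standardize_species)
from .intrinsic import (adaptive_group_threshold, intrinsic_scores,
                        unsupervised_filter)
from .io import (read_expression, read_feature_map, read_gmt, write_expression,
                 write_gmt, write_treeview)
from .normalize import (bridge_normalize, filter_probes, impute_knn,
                        intersect_platforms, median_center_rows)
from .pathways import conserved_pathways, enriched_pathways, score_signatures
from .sam import class_signature
from .synthetic import SyntheticConfig, generate_all

log = logging.getLogger("gemmclass")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    version: str = __version__

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append({
            "stage": stage,
            "timestamp": time.time(),
            "outputs": {str(p.name): _sha256(p) for p in sorted(outputs)},
        })

    def content_digest(self) -> str:
        """Digest over config, seeds, and stage output hashes (no timestamps)."""
        payload = json.dumps({
            "config": self.config, "seeds": self.seeds, "version": self.version,
            "stages": [{"stage": s["stage"], "outputs": s["outputs"]}
                       for s in self.stages],
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, path: Path) -> None:
        data = {"config": self.config, "seeds": self.seeds,
                "version": self.version, "stages": self.stages,
                "content_digest": self.content_digest()}
        Path(path).write_text(json.dumps(data, indent=2))


def _stage_seeds(master: int) -> dict[str, int]:
    """Fan the master seed out to one deterministic seed per stage."""
    names = ("synth", "normalize", "intrinsic", "classes", "signatures",
             "counterparts", "pathways")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


class PipelineError(RuntimeError):
    pass


def run_pipeline(out_dir, config: PipelineConfig | None = None,
                 synthetic: SyntheticConfig | bool | None = None,
                 inputs: dict | None = None, resume: bool = False,
                 co_cluster: bool = False) -> RunManifest:
    """Run all stages on synthetic or file inputs, writing under ``out_dir``.

    ``synthetic`` may be True (defaults) or a :class:`SyntheticConfig`;
    otherwise ``inputs`` must provide paths: ``platforms`` (list of
    expression TSVs with intensity/annotation sidecars), ``bridges`` (JSON
    of platform → bridge sample ids), ``orthologs`` / ``probe_map`` (TSV),
    ``human`` (list of TSVs), ``gmt`` (pathway collection). With ``resume``
    a stage whose outputs already exist is reloaded, not recomputed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=config.to_dict(), seeds=seeds)
    truth = None

    try:
        # --- inputs ---------------------------------------------------------
        if synthetic:
            scfg = synthetic if isinstance(synthetic, SyntheticConfig) \
                else SyntheticConfig(seed=seeds["synth"])
            data = generate_all(scfg)
            platform_bundles = data["mouse"]
            human_bundles = data["human"]
            collection = data["pathways"]
            truth = data["truth"]
            fmap = truth.feature_map
            bridges = truth.bridge_ids
            files = []
            for i, b in enumerate(platform_bundles):
                p = out / f"platform{i + 1}.tsv"
                write_expression(b, p)
                files.append(p)
            truth.to_json(out / "truth.json")
            write_gmt(collection, out / "pathways.gmt")
            manifest.record("synth", files + [out / "truth.json",
                                              out / "pathways.gmt"])
        else:
            if not inputs or "platforms" not in inputs:
                raise PipelineError("no inputs: pass synthetic=True or "
                                    "inputs={'platforms': [...], ...}")
            platform_bundles = [read_expression(p) for p in inputs["platforms"]]
            bridges = json.loads(Path(inputs["bridges"]).read_text())
            if "orthologs" not in inputs:
                raise PipelineError("cross-species stages need --orthologs")
            fmap = read_feature_map(inputs.get("probe_map"), inputs["orthologs"])
            human_bundles = [read_expression(p) for p in inputs.get("human", [])]
            collection = read_gmt(inputs["gmt"]) if inputs.get("gmt") else None

        # --- normalize ------------------------------------------------------
        combined_path = out / "combined.tsv"
        if resume and combined_path.exists():
            combined = read_expression(combined_path)
        else:
            filtered = []
            for b in platform_bundles:
                if b.cy5 is not None:
                    b = filter_probes(b, config.intensity_min, config.presence_min)
                filtered.append(impute_knn(b, config.knn_k))
            filtered = intersect_platforms(filtered)
            bridge_lists = [bridges[str(b.sample_annotations["platform"].iloc[0])]
                            for b in filtered]
            norm = bridge_normalize(filtered, bridge_lists,
                                    pca_r2_max=config.pca_platform_r2_max)
            combined = median_center_rows(norm.combined)
            write_expression(combined, combined_path)
            (out / "pca_report.json").write_text(json.dumps(norm.pca_report))
            manifest.record("normalize", [combined_path, out / "pca_report.json"])

        # --- intrinsic ------------------------------------------------------
        intrinsic_path = out / "intrinsic_genes.txt"
        if resume and intrinsic_path.exists():
            intrinsic_list = intrinsic_path.read_text().split()
        else:
            unsup = unsupervised_filter(combined, config.unsup_min_obs,
                                        config.unsup_abs_log2)
            tree = hcluster(unsup, axis="samples")
            _, groups = adaptive_group_threshold(tree, config.group_r_min)
            result = intrinsic_scores(combined, groups, config.intrinsic_sd_cutoff)
            intrinsic_list = result.selected
            intrinsic_path.write_text("\n".join(intrinsic_list) + "\n")
            result.scores.to_csv(out / "intrinsic_scores.tsv", sep="\t")
            write_treeview(unsup, None, tree, out / "unsupervised")
            manifest.record("intrinsic", [intrinsic_path,
                                          out / "intrinsic_scores.tsv"])

        # --- classes --------------------------------------------------------
        classes_path = out / "classes.tsv"
        cfg_cls = PipelineConfig(**{**config.to_dict(), "seed": seeds["classes"]})
        if resume and classes_path.exists():
            cls_df = pd.read_csv(classes_path, sep="\t", index_col=0)
            labels = cls_df["class"]
            from .classes import ClassAssignment
            assignment = ClassAssignment(
                labels=labels, node_pvalues={},
                class_names=sorted(set(labels) - {UNASSIGNED}))
        else:
            assignment = call_classes(combined, intrinsic_list, cfg_cls)
            pd.DataFrame({"class": assignment.labels}).to_csv(classes_path, sep="\t")
            homog = classify_homogeneity(
                assignment, combined.sample_annotations["model_or_subtype"], config)
            homog.table.to_csv(out / "homogeneity.tsv", sep="\t")
            manifest.record("classes", [classes_path, out / "homogeneity.tsv"])

        # --- class signatures (ortholog gene level) -------------------------
        mouse_genes = collapse_orthologs(combined, fmap)
        signatures = {}
        for i, cname in enumerate(assignment.class_names):
            sig = class_signature(mouse_genes, assignment, cname, config,
                                  seed=seeds["signatures"] + i)
            signatures[cname] = sig
        write_gmt(GeneSetCollection([s for s in signatures.values() if s.genes]),
                  out / "class_signatures.gmt")
        manifest.record("signatures", [out / "class_signatures.gmt"])

        # --- counterparts ---------------------------------------------------
        counterparts = None
        if human_bundles:
            named = {str(h.sample_annotations["platform"].iloc[0]): h
                     for h in human_bundles}
            cfg_cp = PipelineConfig(**{**config.to_dict(),
                                       "seed": seeds["counterparts"]})
            counterparts, _ = counterpart_gsa(signatures, named, cfg_cp)
            counterparts.to_tsv(out / "counterparts.tsv")
            manifest.record("counterparts", [out / "counterparts.tsv"])

            if co_cluster:
                m_std = standardize_species(mouse_genes)
                h_std = standardize_species(_concat_human(human_bundles))
                merged = merge_species(m_std, h_std)
                mtree = hcluster(merged, axis="samples")
                write_treeview(merged, None, mtree, out / "cocluster")
                manifest.record("cocluster", [out / "cocluster.cdt"])

        # --- pathways -------------------------------------------------------
        if collection is not None and human_bundles:
            common = mouse_genes.values.index
            for h in human_bundles:
                common = common.intersection(h.values.index)
            mouse_common = mouse_genes.subset_features(common)
            mouse_scores = score_signatures(mouse_common, collection)
            mouse_enriched = {}
            for i, cname in enumerate(assignment.class_names):
                members = assignment.labels == cname
                mouse_enriched[cname] = enriched_pathways(
                    mouse_scores, members.to_numpy(), config,
                    seed=seeds["pathways"] + i, set_id=cname)
            human_enriched: dict[str, dict[str, list[str]]] = {}
            for k, h in enumerate(human_bundles):
                ds = str(h.sample_annotations["platform"].iloc[0])
                scores = score_signatures(h.subset_features(common), collection)
                per_subtype = {}
                subtypes = sorted(h.sample_annotations["model_or_subtype"].unique())
                for j, sub in enumerate(subtypes):
                    y = (h.sample_annotations["model_or_subtype"] == sub).to_numpy()
                    per_subtype[sub] = enriched_pathways(
                        scores, y, config, seed=seeds["pathways"] + 100 + 10 * k + j,
                        set_id=f"{ds}:{sub}").genes
                human_enriched[ds] = per_subtype
            pairs = counterparts.called_pairs() if counterparts else []
            conserved = conserved_pathways(
                {c: s.genes for c, s in mouse_enriched.items()},
                human_enriched, pairs)
            rows = [(c, s, len(v), ";".join(v)) for (c, s), v in conserved.items()]
            pd.DataFrame(rows, columns=["class", "subtype", "n_conserved",
                                        "pathways"]).to_csv(
                out / "conserved_pathways.tsv", sep="\t", index=False)
            manifest.record("pathways", [out / "conserved_pathways.tsv"])

        # --- report ---------------------------------------------------------
        report_path = out / "report.md"
        report_path.write_text(render_report(assignment, out))
        manifest.record("report", [report_path])
    except Exception as err:
        manifest.write(out / "manifest.json")
        raise PipelineError(f"stage failed: {err}") from err

    manifest.write(out / "manifest.json")
    return manifest


def _concat_human(bundles: list[ExpressionBundle]) -> ExpressionBundle:
    common = bundles[0].values.index
    for b in bundles[1:]:
        common = common.intersection(b.values.index)
    values = pd.concat([b.values.loc[common] for b in bundles], axis=1)
    ann = pd.concat([b.sample_annotations for b in bundles])
    return ExpressionBundle(values, ann)


def render_report(assignment, out_dir: Path) -> str:
    """Deterministic run summary: class sizes, homogeneity, counterparts."""
    out = Path(out_dir)
    lines = ["# Run summary", ""]
    sizes = assignment.class_sizes
    if len(sizes) == 0:
        lines.append("No expression class was called.")
    else:
        lines.append(f"{len(sizes)} classes; "
                     f"{assignment.n_assigned}/{len(assignment.labels)} samples assigned.")
        lines.append("")
        lines.append("| class | n |")
        lines.append("|---|---|")
        for name, n in sizes.items():
            lines.append(f"| {name} | {n} |")
    homog = out / "homogeneity.tsv"
    if homog.exists():
        lines += ["", "## Model homogeneity", "",
                  pd.read_csv(homog, sep="\t").to_markdown(index=False)]
    cp = out / "counterparts.tsv"
    if cp.exists():
        lines += ["", "## Counterparts (see counterparts.tsv)", ""]
        df = pd.read_csv(cp, sep="\t", header=[0, 1], index_col=0)
        lines.append(df.iloc[:, -1].rename("counterpart").fillna("-").to_markdown())
    cons = out / "conserved_pathways.tsv"
    if cons.exists():
        df = pd.read_csv(cons, sep="\t")
        lines += ["", "## Conserved pathways", "",
                  df[["class", "subtype", "n_conserved"]].to_markdown(index=False)]
    return "\n".join(lines) + "\n"
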