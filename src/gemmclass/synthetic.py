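"""Synthetic multi-platform, cross-species expression cohorts with known truth.

Emulates the statistical structure the pipeline assumes: three two-color
array platforms with per-probe additive offsets, bridge tumors from two
homogeneous models profiled on every platform, mouse models that are
homogeneous / semi-homogeneous / heterogeneous mixtures over latent
expression classes, three human cohorts with six subtypes, ortholog-linked
shared programs between selected mouse classes and human subtypes, and a
pathway collection with planted class-specific enrichment.

Values are additive in log2 space: class mean (0 baseline, +delta on the
class's signature genes) + per-probe platform offset + Gaussian noise,
masked missing completely at random. Channel intensities consistent with
the ratios are emitted so the intensity filter is exercisable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle, FeatureMap, GeneSet, GeneSetCollection
from .classes import HETEROGENEOUS, HOMOGENEOUS, SEMI_HOMOGENEOUS

SUBTYPE_NAMES = ("basal-like", "claudin-low", "her2-enriched",
                 "luminal-a", "luminal-b", "normal-like")


class SyntheticConfigError(ValueError):
    pass


@dataclass
class ModelSpec:
    """A mouse model: a mixture over latent classes and a tumor count."""

    name: str
    weights: tuple[float, ...]
    n_tumors: int


def default_models() -> list[ModelSpec]:
    """Six-class roster with two homogeneous bridge models, further
    homogeneous and semi-homogeneous models, and one heterogeneous model."""
    return [
        ModelSpec("NeuSim", (1.0, 0, 0, 0, 0, 0), 12),
        ModelSpec("TagSim", (0, 1.0, 0, 0, 0, 0), 12),
        ModelSpec("MycSim", (0, 0, 0.9, 0.1, 0, 0), 10),
        ModelSpec("WntEarlySim", (0, 0, 0, 1.0, 0, 0), 10),
        ModelSpec("WntSemiSim", (0, 0, 0, 0.55, 0.40, 0.05), 12),
        ModelSpec("SquamSim", (0, 0, 0, 0, 0.9, 0.1), 10),
        ModelSpec("ClaudinSim", (0, 0, 0, 0, 0.05, 0.95), 10),
        ModelSpec("HetSim", (0.2, 0.1, 0.2, 0.1, 0.1, 0.3), 14),
    ]


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    two_probe_fraction: float = 0.2
    n_platforms: int = 3
    platform_offset_sd: float = 0.5
    platform_probe_keep: float = 0.95
    mouse_classes: int = 6
    class_signature_size: int = 60
    effect_size_delta: float = 2.0
    noise_sd: float = 1.0
    t_noise_df: int | None = None          # heavy-tail switch for robustness tests
    models: list[ModelSpec] = field(default_factory=default_models)
    bridge_models: tuple[str, str] = ("NeuSim", "TagSim")
    n_bridge_per_platform: tuple[int, int] = (5, 5)
    human_datasets: tuple[tuple[str, int], ...] = (
        ("humanA", 100), ("humanB", 100), ("humanC", 100))
    n_subtypes: int = 6
    shared_programs: tuple[tuple[int, int, int], ...] = ((0, 0, 40), (1, 1, 40),
                                                         (2, 2, 40))
    ortholog_fraction: float = 0.9
    n_human_only_genes: int = 200
    n_pathways: int = 200
    planted_per_class: int = 5
    pathway_size: int = 40
    planted_signature_members: int = 30
    missing_rate: float = 0.02
    intensity_fail_rate: float = 0.01
    latency_early_class: int = 3
    latency_late_class: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.models:
            if len(m.weights) != self.mouse_classes:
                raise SyntheticConfigError(
                    f"model {m.name}: {len(m.weights)} weights for "
                    f"{self.mouse_classes} classes")
            if abs(sum(m.weights) - 1.0) > 1e-8:
                raise SyntheticConfigError(
                    f"model {m.name}: mixture weights sum to {sum(m.weights)}")
            if m.n_tumors < 1:
                raise SyntheticConfigError(f"model {m.name}: n_tumors < 1")
        if self.mouse_classes * self.class_signature_size > self.n_genes:
            raise SyntheticConfigError("class signatures exceed the gene universe")
        names = {m.name for m in self.models}
        for b in self.bridge_models:
            if b not in names:
                raise SyntheticConfigError(f"bridge model {b!r} not in roster")
        for c, s, k in self.shared_programs:
            if not 0 <= c < self.mouse_classes:
                raise SyntheticConfigError(f"shared program references class {c}")
            if not 0 <= s < self.n_subtypes:
                raise SyntheticConfigError(f"shared program references subtype {s}")
            if k > self.class_signature_size:
                raise SyntheticConfigError(
                    f"shared program of {k} genes exceeds the class signature")
        if self.n_pathways and self.n_pathways < self.planted_per_class * self.mouse_classes:
            raise SyntheticConfigError("n_pathways below the planted count")
        if self.pathway_size > self.n_genes:
            raise SyntheticConfigError("pathway size exceeds gene universe")
        if not 0 <= self.missing_rate < 1:
            raise SyntheticConfigError("missing_rate must be in [0, 1)")
        if self.n_subtypes != len(SUBTYPE_NAMES):
            raise SyntheticConfigError(f"n_subtypes must be {len(SUBTYPE_NAMES)}")

    @property
    def class_names(self) -> list[str]:
        return [f"mclass{k + 1}" for k in range(self.mouse_classes)]

    @property
    def subtype_names(self) -> list[str]:
        return list(SUBTYPE_NAMES[:self.n_subtypes])


@dataclass
class SyntheticTruth:
    """Planted ground truth: the acceptance surface for recovery tests."""

    class_of_sample: dict[str, str] = field(default_factory=dict)
    subtype_of_sample: dict[str, str] = field(default_factory=dict)
    signature_genes: dict[str, list[str]] = field(default_factory=dict)
    human_signature_genes: dict[str, list[str]] = field(default_factory=dict)
    shared_program_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    enriched_pathways: dict[str, list[str]] = field(default_factory=dict)
    model_category: dict[str, str] = field(default_factory=dict)
    platform_offsets: pd.DataFrame | None = None
    feature_map: FeatureMap | None = None
    bridge_ids: dict[str, list[str]] = field(default_factory=dict)
    class_names: list[str] = field(default_factory=list)
    subtype_names: list[str] = field(default_factory=list)

    def linked_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.shared_program_genes)

    def to_json(self, path) -> None:
        data = {
            "class_of_sample": self.class_of_sample,
            "subtype_of_sample": self.subtype_of_sample,
            "signature_genes": self.signature_genes,
            "human_signature_genes": self.human_signature_genes,
            "shared_program_genes": {f"{c}|{s}": g for (c, s), g
                                     in self.shared_program_genes.items()},
            "enriched_pathways": self.enriched_pathways,
            "model_category": self.model_category,
            "platform_offsets": (None if self.platform_offsets is None
                                 else self.platform_offsets.to_dict()),
            "probe_to_gene": self.feature_map.probe_to_gene if self.feature_map else {},
            "orthologs": self.feature_map.orthologs if self.feature_map else {},
            "bridge_ids": self.bridge_ids,
            "class_names": self.class_names,
            "subtype_names": self.subtype_names,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            class_of_sample=data["class_of_sample"],
            subtype_of_sample=data["subtype_of_sample"],
            signature_genes=data["signature_genes"],
            human_signature_genes=data["human_signature_genes"],
            shared_program_genes={tuple(k.split("|")): v for k, v
                                  in data["shared_program_genes"].items()},
            enriched_pathways=data["enriched_pathways"],
            model_category=data["model_category"],
            platform_offsets=(None if data["platform_offsets"] is None
                              else pd.DataFrame(data["platform_offsets"])),
            feature_map=FeatureMap(data["probe_to_gene"], data["orthologs"]),
            bridge_ids=data["bridge_ids"],
            class_names=data["class_names"],
            subtype_names=data["subtype_names"],
        )


def _apportion(weights, n: int) -> list[int]:
    """Largest-remainder apportionment of n tumors over class weights."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return list(counts)


def _noise(rng, size, sd, t_df):
    if t_df is None:
        return rng.normal(0.0, sd, size=size)
    scale = sd / np.sqrt(t_df / (t_df - 2))
    return rng.standard_t(t_df, size=size) * scale


def _mouse_gene(i: int) -> str:
    return f"mGene{i:04d}"


def _human_gene(i: int) -> str:
    return f"HGENE{i:04d}"


def _build_universe(config: SyntheticConfig, rng) -> tuple[FeatureMap, dict]:
    """Gene universe, probe map, ortholog map, and planted gene programs."""
    genes = [_mouse_gene(i) for i in range(config.n_genes)]
    n_orth = int(round(config.ortholog_fraction * config.n_genes))
    orth_idx = np.sort(rng.choice(config.n_genes, size=n_orth, replace=False))
    orthologs = {_mouse_gene(i): _human_gene(i) for i in orth_idx}

    # signatures drawn from the ortholog pool: disjoint blocks of a permutation
    perm = rng.permutation(orth_idx)
    signature_genes: dict[str, list[str]] = {}
    shared: dict[tuple[str, str], list[str]] = {}
    pos = 0
    for k, cname in enumerate(config.class_names):
        block = perm[pos:pos + config.class_signature_size]
        pos += config.class_signature_size
        signature_genes[cname] = [_mouse_gene(i) for i in np.sort(block)]
    for c, s, k in config.shared_programs:
        cname, sname = config.class_names[c], config.subtype_names[s]
        sig = signature_genes[cname]
        if k > len(sig):
            raise SyntheticConfigError(
                f"shared program ({cname},{sname}) larger than the ortholog pool "
                f"of the class signature ({k} > {len(sig)})")
        chosen = rng.choice(len(sig), size=k, replace=False)
        shared[(cname, sname)] = sorted(orthologs[sig[i]] for i in chosen)

    used = {g for sig in signature_genes.values() for g in sig}
    free_orth = [g for g in ( _mouse_gene(i) for i in orth_idx) if g not in used]
    free_perm = rng.permutation(len(free_orth))
    human_signature: dict[str, list[str]] = {}
    pos = 0
    for sname in config.subtype_names:
        take = free_perm[pos:pos + config.class_signature_size]
        pos += config.class_signature_size
        if len(take) < config.class_signature_size:
            raise SyntheticConfigError("ortholog pool too small for human signatures")
        human_signature[sname] = sorted(orthologs[free_orth[i]] for i in take)

    probes: list[str] = []
    probe_to_gene: dict[str, str] = {}
    two = rng.random(config.n_genes) < config.two_probe_fraction
    for i, g in enumerate(genes):
        for j in range(2 if two[i] else 1):
            p = f"{g}_p{j + 1}"
            probes.append(p)
            probe_to_gene[p] = g
    fmap = FeatureMap(probe_to_gene, orthologs)
    return fmap, {"genes": genes, "probes": probes,
                  "signature_genes": signature_genes,
                  "human_signature_genes": human_signature,
                  "shared": shared, "orth_idx": orth_idx}


def generate_mouse_cohort(config: SyntheticConfig | None = None
                          ) -> tuple[list[ExpressionBundle], SyntheticTruth]:
    """Per-platform mouse bundles (with channel intensities) plus truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    fmap, uni = _build_universe(config, rng)
    probes = uni["probes"]
    n_probes = len(probes)
    platform_names = [f"platform{t + 1}" for t in range(config.n_platforms)]

    offsets = rng.normal(0.0, config.platform_offset_sd,
                         size=(n_probes, config.n_platforms))
    offsets_df = pd.DataFrame(offsets, index=probes, columns=platform_names)

    # class mean per probe: +delta on the class's signature genes
    gene_of = np.array([fmap.probe_to_gene[p] for p in probes])
    class_mean = np.zeros((n_probes, config.mouse_classes))
    for k, cname in enumerate(config.class_names):
        sig = set(uni["signature_genes"][cname])
        class_mean[np.isin(gene_of, list(sig)), k] = config.effect_size_delta

    truth = SyntheticTruth(
        signature_genes=uni["signature_genes"],
        human_signature_genes=uni["human_signature_genes"],
        shared_program_genes=uni["shared"],
        platform_offsets=offsets_df, feature_map=fmap,
        class_names=config.class_names, subtype_names=config.subtype_names)

    lat_mean = np.full(config.mouse_classes, 15.0)
    lat_sd = np.full(config.mouse_classes, 4.0)
    early, late = config.latency_early_class, config.latency_late_class
    if early is not None and early < config.mouse_classes:
        lat_mean[early], lat_sd[early] = 9.0, 1.5
    if late is not None and late < config.mouse_classes:
        lat_mean[late], lat_sd[late] = 22.0, 3.0

    # roster: (sample id, model, class index, platform index, is_bridge)
    roster: list[tuple[str, str, int, int, bool]] = []
    for m in config.models:
        counts = _apportion(m.weights, m.n_tumors)
        top = max(counts) / m.n_tumors
        top_two = sum(sorted(counts)[-2:]) / m.n_tumors
        truth.model_category[m.name] = (
            HOMOGENEOUS if top >= 0.9 else
            SEMI_HOMOGENEOUS if top_two >= 0.9 else HETEROGENEOUS)
        classes = [k for k, c in enumerate(counts) for _ in range(c)]
        platforms = rng.permutation(
            np.arange(m.n_tumors) % config.n_platforms)
        for i, (k, t) in enumerate(zip(classes, platforms)):
            roster.append((f"{m.name}_t{i + 1:02d}", m.name, k, int(t), False))
    bridge_of_model = dict(zip(config.bridge_models, config.n_bridge_per_platform))
    model_class = {m.name: int(np.argmax(m.weights)) for m in config.models}
    for t, pname in enumerate(platform_names):
        ids = []
        for bmodel, nb in bridge_of_model.items():
            for i in range(nb):
                sid = f"{bmodel}_b{t + 1}_{i + 1}"
                roster.append((sid, bmodel, model_class[bmodel], t, True))
                ids.append(sid)
        truth.bridge_ids[pname] = ids

    # per-platform probe subsets (platforms do not share every probe)
    keep_idx = []
    for t in range(config.n_platforms):
        k = int(round(config.platform_probe_keep * n_probes))
        keep_idx.append(np.sort(rng.choice(n_probes, size=k, replace=False)))

    bundles = []
    for t, pname in enumerate(platform_names):
        members = [r for r in roster if r[3] == t]
        sample_ids = [r[0] for r in members]
        cls = np.array([r[2] for r in members])
        rows = keep_idx[t]
        signal = class_mean[np.ix_(rows, cls)] + offsets[rows, t][:, None]
        noise = _noise(rng, signal.shape, config.noise_sd, config.t_noise_df)
        vals = signal + noise
        if config.missing_rate > 0:
            vals[rng.random(vals.shape) < config.missing_rate] = np.nan
        values = pd.DataFrame(vals, index=[probes[i] for i in rows],
                              columns=sample_ids)
        cy3 = np.exp2(rng.uniform(5.0, 11.0, size=vals.shape))
        if config.intensity_fail_rate > 0:
            weak = rng.random(vals.shape) < config.intensity_fail_rate
            cy3[weak] = rng.uniform(1.0, 9.0, size=int(weak.sum()))
        with np.errstate(invalid="ignore"):
            cy5 = cy3 * np.exp2(np.where(np.isfinite(vals), vals, 0.0))
        ann = pd.DataFrame({
            "species": "mouse",
            "model_or_subtype": [r[1] for r in members],
            "platform": pname,
            "is_bridge": [r[4] for r in members],
            "latency_weeks": [float(np.clip(rng.normal(lat_mean[r[2]], lat_sd[r[2]]),
                                            3.0, None)) for r in members],
        }, index=sample_ids)
        bundles.append(ExpressionBundle(
            values, ann,
            pd.DataFrame(cy5, index=values.index, columns=sample_ids),
            pd.DataFrame(cy3, index=values.index, columns=sample_ids)))
        for r in members:
            truth.class_of_sample[r[0]] = config.class_names[r[2]]
    return bundles, truth


def generate_human_cohorts(config: SyntheticConfig, truth: SyntheticTruth
                           ) -> tuple[list[ExpressionBundle], SyntheticTruth]:
    """Three gene-level human cohorts with planted subtype and shared programs."""
    rng = np.random.default_rng(config.seed + 101)
    orth_idx = [int(h[5:]) for h in truth.feature_map.orthologs.values()]
    genes = sorted({_human_gene(i) for i in orth_idx} |
                   {f"HONLY{i:04d}" for i in range(config.n_human_only_genes)})
    gene_pos = {g: i for i, g in enumerate(genes)}

    elevated = {s: set(truth.human_signature_genes[s]) for s in config.subtype_names}
    for (cname, sname), program in truth.shared_program_genes.items():
        elevated[sname] |= set(program)

    bundles = []
    for ds, n_samples in config.human_datasets:
        subtype_idx = np.array([i % config.n_subtypes for i in range(n_samples)])
        subtype_idx = subtype_idx[rng.permutation(n_samples)]
        sample_ids = [f"{ds}_s{i + 1:03d}" for i in range(n_samples)]
        vals = _noise(rng, (len(genes), n_samples), config.noise_sd,
                      config.t_noise_df)
        for s, sname in enumerate(config.subtype_names):
            cols = np.where(subtype_idx == s)[0]
            rows = [gene_pos[g] for g in elevated[sname] if g in gene_pos]
            vals[np.ix_(rows, cols)] += config.effect_size_delta
        ann = pd.DataFrame({
            "species": "human",
            "model_or_subtype": [config.subtype_names[s] for s in subtype_idx],
            "platform": ds, "is_bridge": False, "latency_weeks": np.nan,
        }, index=sample_ids)
        bundles.append(ExpressionBundle(
            pd.DataFrame(vals, index=genes, columns=sample_ids), ann))
        for sid, s in zip(sample_ids, subtype_idx):
            truth.subtype_of_sample[sid] = config.subtype_names[s]
    return bundles, truth


def generate_pathway_collection(config: SyntheticConfig, truth: SyntheticTruth
                                ) -> GeneSetCollection:
    """Pathway collection with ``planted_per_class`` enriched pathways per
    class (>= 50% of members from the class signature's orthologs)."""
    rng = np.random.default_rng(config.seed + 202)
    if config.n_pathways == 0:
        return GeneSetCollection([])
    orthologs = truth.feature_map.orthologs
    sig_orth = {c: [orthologs[g] for g in sig if g in orthologs]
                for c, sig in truth.signature_genes.items()}
    all_sig = {h for hs in sig_orth.values() for h in hs}
    background = sorted(set(orthologs.values()) - all_sig)

    sets = []
    pw = 0
    for cname in truth.class_names:
        linked = [prog for (c, s), prog in truth.shared_program_genes.items()
                  if c == cname]
        pool = linked[0] if linked else sig_orth[cname]
        truth.enriched_pathways[cname] = []
        for _ in range(config.planted_per_class):
            k = min(config.planted_signature_members, len(pool))
            members = list(rng.choice(pool, size=k, replace=False))
            pad = rng.choice(background, size=config.pathway_size - k, replace=False)
            pw += 1
            pid = f"PW{pw:04d}"
            sets.append(GeneSet(pid, f"planted for {cname}",
                                sorted(members) + sorted(pad)))
            truth.enriched_pathways[cname].append(pid)
    while pw < config.n_pathways:
        size = int(rng.integers(20, 61))
        members = sorted(rng.choice(background, size=size, replace=False))
        pw += 1
        sets.append(GeneSet(f"PW{pw:04d}", "background", members))
    return GeneSetCollection(sets)


def generate_all(config: SyntheticConfig | None = None) -> dict:
    """Mouse bundles, human cohorts, pathway collection, and truth in one call."""
    config = config or SyntheticConfig()
    mouse, truth = generate_mouse_cohort(config)
    human, truth = generate_human_cohorts(config, truth)
    pathways = generate_pathway_collection(config, truth)
    return {"config": config, "mouse": mouse, "human": human,
            "pathways": pathways, "truth": truth}
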