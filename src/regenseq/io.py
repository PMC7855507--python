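"""TSV readers/writers, run configuration, and the end-to-end pipeline.

All tabular exchange is TSV with required headers so outputs stay diffable;
the pipeline driver chains simulate -> de -> consensus -> enrich -> celltype
-> profiles and emits a JSON run manifest with per-file checksums and the
warnings each stage surfaced (unmapped IDs, sub-background genes, sign
conflicts).  Reruns with the same config and seed produce byte-identical
TSV outputs; manifests differ only in timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .celltype import (
    CellTypeReference,
    background_filter,
    cluster_profiles,
    map_ids,
    percentage_profiles,
    top_unique,
)
from .consensus import Thresholds, threshold_filter, venn_counts, vote
from .de import CountMatrix, DEResult, fpkm_matrix, run_de_suite
from .enrich import binomial_overrep, bonferroni_adjust, significant_categories
from .profiles import build_profile_table
from .synth import (
    SimulationConfig,
    simulate_annotation,
    simulate_celltype_reference,
    simulate_counts,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "PipelineError",
    "read_count_matrix",
    "read_metadata",
    "read_gene_lengths",
    "read_annotation",
    "read_celltype_reference",
    "write_tsv",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, metadata: str | Path | pd.Series) -> CountMatrix:
    """Read a gene x sample count TSV plus sample metadata.

    The TSV has gene IDs in the first column and sample IDs in the header.
    ``metadata`` is either a TSV with columns sample and group or a Series
    mapping sample ID to group.  Non-integer cells and duplicate gene IDs
    are rejected with the offending location/ID.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-integer count at gene {df.index[i]!r}, sample {col!r} "
                f"(row {i + 2}, column {j + 2}): {df.iloc[i, j]!r}"
            )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes}")
    groups = metadata if isinstance(metadata, pd.Series) else read_metadata(metadata)
    return CountMatrix(counts=df.astype(np.int64), groups=groups)


def read_metadata(path: str | Path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(meta.columns):
        raise ValueError("metadata needs 'sample' and 'group' columns")
    return meta.set_index("sample")["group"]


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length"} <= set(df.columns):
        raise ValueError("gene length table needs 'gene_id' and 'length' columns")
    lengths = df.set_index("gene_id")["length"]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return lengths


def read_annotation(path: str | Path, universe: set | None = None,
                    names_path: str | Path | None = None):
    """Two-column TSV (category_id, gene_id) -> AnnotationMap."""
    from .enrich import AnnotationMap

    df = pd.read_csv(path, sep="\t")
    if not {"category_id", "gene_id"} <= set(df.columns):
        raise ValueError("annotation needs 'category_id' and 'gene_id' columns")
    cats = {c: set(g) for c, g in df.groupby("category_id")["gene_id"]}
    if universe is None:
        universe = set(df["gene_id"])
    names = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t")
        names = dict(zip(nd["category_id"], nd["name"]))
    return AnnotationMap(categories=cats, reference_genes=universe, names=names)


def read_celltype_reference(path: str | Path, id_map_path: str | Path) -> CellTypeReference:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    id_map = pd.read_csv(id_map_path, sep="\t")
    return CellTypeReference(expression=expr, id_map=id_map)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# run configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic run."""

    out_dir: str = "regenseq_run"
    seed: int = 0
    timepoints: tuple = ("+1d", "+3d")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_support: int = 2
    alpha: float = 0.05
    background_threshold: float = 0.1
    n_candidates: int = 20

    def __post_init__(self) -> None:
        if not 1 <= len(self.timepoints) <= 3:
            raise ValueError("between 1 and 3 timepoints supported")


@dataclass
class RunManifest:
    version: str
    config: dict
    outputs: dict = field(default_factory=dict)   # relative path -> sha256
    warnings: dict = field(default_factory=dict)  # stage -> counts
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimulationConfig(**raw.pop("simulation", {}))
    thr = Thresholds(**raw.pop("thresholds", {}))
    if "timepoints" in raw:
        raw["timepoints"] = tuple(raw["timepoints"])
    return RunConfig(simulation=sim, thresholds=thr, **raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _simulate_contrast(sim: SimulationConfig, seed: int):
    cfg = sim.replace(seed=seed)
    injured, control, truth = simulate_counts(cfg)
    return CountMatrix.concat(injured, control), truth


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the full synthetic pipeline and write all stage outputs.

    Each timepoint is an independent injured-vs-control simulation (seed
    derived from the run seed); consensus sets feed the Venn overlay, the
    category enrichment, the cell-type association, and the candidate-gene
    profile table.  Returns the run manifest (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config={
            **asdict(config),
            "simulation": asdict(config.simulation),
            "thresholds": asdict(config.thresholds),
        },
        started=datetime.now(timezone.utc).isoformat(),
    )
    outputs: list[Path] = []

    def record(path: Path) -> None:
        outputs.append(path)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    rng = np.random.default_rng(config.seed)
    consensus_sets = {}
    truths = {}
    matrices = {}

    with stage("simulate+de+consensus"):
        for i, tp in enumerate(config.timepoints):
            cm, truth = _simulate_contrast(config.simulation, config.seed + i)
            truths[tp] = truth
            matrices[tp] = cm
            record(write_tsv(cm.counts, out / f"counts_{_slug(tp)}.tsv"))
            results = run_de_suite(cm, test_group="injured")
            filtered = {}
            for method_id, res in results.items():
                tab = res.table.copy()
                tab["method_id"] = method_id
                record(write_tsv(tab, out / f"de_{_slug(tp)}_{method_id}.tsv"))
                filtered[method_id] = threshold_filter(res, config.thresholds)
            cs = vote(filtered, min_support=config.min_support, label=tp)
            consensus_sets[tp] = cs
            record(write_tsv(cs.table, out / f"consensus_{_slug(tp)}.tsv"))
            manifest.warnings.setdefault("sign_conflicts", {})[tp] = len(cs.conflicts)

    with stage("venn"):
        if len(consensus_sets) >= 2:
            regions = venn_counts({tp: cs.genes for tp, cs in consensus_sets.items()})
            rows = [
                ("+".join(sorted(k)) if isinstance(k, frozenset) else k, v)
                for k, v in regions.items()
            ]
            record(write_tsv(
                pd.DataFrame(rows, columns=["region", "count"]),
                out / "venn_regions.tsv", index=False,
            ))

    with stage("enrich"):
        first_tp = config.timepoints[0]
        ann = simulate_annotation(
            config.simulation.replace(seed=config.seed), truths[first_tp]
        ).with_unclassified()
        ann_rows = [
            (c, g) for c, genes in sorted(ann.categories.items()) for g in sorted(genes)
        ]
        record(write_tsv(
            pd.DataFrame(ann_rows, columns=["category_id", "gene_id"]),
            out / "annotation.tsv", index=False,
        ))
        for tp, cs in consensus_sets.items():
            if not cs.genes:
                logger.info("no consensus genes at %s; enrichment skipped", tp)
                continue
            res = bonferroni_adjust(binomial_overrep(cs.genes, ann))
            sig = significant_categories(res, alpha=config.alpha)
            record(write_tsv(res, out / f"enrichment_{_slug(tp)}.tsv"))
            record(write_tsv(sig, out / f"enrichment_significant_{_slug(tp)}.tsv"))

    with stage("celltype"):
        ref, ct_truth = simulate_celltype_reference(
            config.simulation.replace(seed=config.seed)
        )
        record(write_tsv(ref.expression, out / "celltype_reference.tsv"))
        record(write_tsv(ref.id_map, out / "celltype_id_map.tsv", index=False))
        profile_frames = []
        for tp, cs in consensus_sets.items():
            if not cs.genes:
                continue
            mapping, dropped = map_ids(cs.genes, ref)
            manifest.warnings.setdefault("unmapped_ids", {})[tp] = len(dropped)
            if mapping.empty:
                continue
            mapping, excluded = background_filter(
                mapping, ref, config.background_threshold
            )
            manifest.warnings.setdefault("below_background", {})[tp] = len(excluded)
            if mapping.empty:
                continue
            prof = percentage_profiles(mapping, ref)
            clusters = cluster_profiles(prof)
            ordered = prof.loc[clusters["all"].order].copy()
            ordered.insert(0, "timepoint", tp)
            profile_frames.append(ordered)
        if profile_frames:
            record(write_tsv(
                pd.concat(profile_frames), out / "celltype_profiles.tsv"
            ))
        if len(config.timepoints) >= 2:
            tps = list(config.timepoints)
            for tp in tps:
                others = set().union(
                    *(consensus_sets[o].genes for o in tps if o != tp)
                )
                uniq = consensus_sets[tp].genes - others
                if not uniq:
                    continue
                lfc = consensus_sets[tp].table.loc[sorted(uniq), "avg_log2fc"]
                up, down = top_unique(lfc)
                tab = pd.concat([
                    up.to_frame().assign(direction="up"),
                    down.to_frame().assign(direction="down"),
                ])
                tab.insert(0, "timepoint", tp)
                record(write_tsv(tab, out / f"top_unique_{_slug(tp)}.tsv"))

    with stage("profiles"):
        lengths = pd.Series(
            rng.integers(200, 10_000, size=config.simulation.n_genes),
            index=truths[config.timepoints[0]].gene_ids, name="length",
        )
        record(write_tsv(lengths.to_frame(), out / "gene_lengths.tsv"))
        first = config.timepoints[0]
        truth0 = truths[first]
        de_genes = list(truth0.gene_ids[truth0.de_flags])
        non_de = list(truth0.gene_ids[~truth0.de_flags])
        candidates = (de_genes + non_de)[: config.n_candidates]
        group_fpkm = {}
        injury_calls = {}
        for tp in config.timepoints:
            cm = matrices[tp]
            fp = fpkm_matrix(cm, lengths)
            for grp in ("control", "injured"):
                cols = cm.groups.index[cm.groups == grp]
                group_fpkm[f"{grp}_{tp}"] = fp[cols]
            injury_calls[f"injured_{tp}"] = consensus_sets[tp]
        development_calls = None
        if len(config.timepoints) >= 2:
            last = config.timepoints[-1]
            young = matrices[first]
            old = matrices[last]
            y_cols = young.groups.index[young.groups == "control"]
            o_cols = old.groups.index[old.groups == "control"]
            dev_cm = CountMatrix(
                counts=pd.concat(
                    [
                        young.counts[y_cols].rename(columns=lambda c: f"young_{c}"),
                        old.counts[o_cols].rename(columns=lambda c: f"old_{c}"),
                    ],
                    axis=1,
                ),
                groups=pd.Series(
                    ["ctl_young"] * len(y_cols) + ["ctl_old"] * len(o_cols),
                    index=[f"young_{c}" for c in y_cols] + [f"old_{c}" for c in o_cols],
                ),
            )
            dev_results = run_de_suite(dev_cm, test_group="ctl_old")
            dev_filtered = {
                mid: threshold_filter(res, config.thresholds)
                for mid, res in dev_results.items()
            }
            development_calls = vote(
                dev_filtered, min_support=config.min_support, label="development"
            )
        table = build_profile_table(
            candidates, group_fpkm, injury_calls, development_calls
        )
        record(write_tsv(table.values, out / "profile_values.tsv"))
        record(write_tsv(table.scaled_values, out / "profile_scaled.tsv"))
        flags = table.injury_flags.copy()
        flags["development"] = table.development_flags
        record(write_tsv(flags, out / "profile_flags.tsv"))
        manifest.warnings["missing_candidates"] = len(table.missing)

    for p in outputs:
        manifest.outputs[str(p.relative_to(out))] = _checksum(p)
    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in label).strip("_")
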