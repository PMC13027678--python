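"""End-to-end analysis pipeline: run every stage, write artifacts + manifest.

``analyze`` takes a corpus and a :class:`RunConfig`, runs the length
descriptives, pairwise similarity matrices with dendrograms, group
edit-operation summaries, TF-IDF group profiles, topic profiles, variant
entropies, redundancy tables, statistical tests and the bootstrap sensitivity
analysis, and writes each as CSV/JSON under the output directory together with
a machine-readable manifest (artifact list, config hash, seeds).  Stages that
need multiple groups are skipped with an explicit manifest notice when the
corpus has only one group; the variant-entropy stage is skipped when no
dictionary is supplied; the embedding-similarity metric runs only when a
backend is injected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import GroupedCorpus
from .lexical import GroupTfidfProfiler
from .redundancy import group_redundancy, RedundancyProfiler
from .similarity import (EmbeddingBackend, WardClusterer,
                         all_group_edit_summaries, pairwise_matrix)
from .stats import bootstrap_downsample, describe_lengths, length_test_table, note_length
from .topics import GroupTopicModel
from .variation import VariantDictionary, group_entropy_table

log = logging.getLogger("notestyle")


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("notestyle")
    except PackageNotFoundError:
        return "unknown"

__all__ = ["RunConfig", "analyze", "render_report"]


@dataclass
class RunConfig:
    """Structured configuration of one analysis run."""

    output_dir: str = "notestyle_out"
    metrics: tuple[str, ...] = ("ter", "bleu", "rouge_l")
    n_clusters: int = 4
    n_topics: int = 3
    topic_seed: int = 0
    compressor_level: int = 6
    bootstrap_B: int = 1000
    bootstrap_n_target: int = 4
    bootstrap_seed: int = 0
    length_unit: str = "tokens"
    tfidf_variant: str = "paper_formula"
    top_k_terms: int = 10
    variant_concepts: tuple[str, ...] = ()

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> str:
    df.to_csv(path, **kwargs)
    return path.name


def _write_json(obj, path: Path) -> str:
    path.write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")
    return path.name


def analyze(corpus: GroupedCorpus, config: RunConfig,
            dictionary: VariantDictionary | None = None,
            embedding_backend: EmbeddingBackend | None = None) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version(),
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {"topic_seed": config.topic_seed,
                  "bootstrap_seed": config.bootstrap_seed},
        "n_notes": len(corpus),
        "groups": {g: len(ns) for g, ns in corpus.groups().items()},
        "artifacts": {},
        "skipped": [],
    }
    multi_group = len(corpus.groups()) >= 2

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return deco

    @stage("lengths")
    def _lengths():
        df = describe_lengths(corpus, unit=config.length_unit)
        manifest["artifacts"]["lengths"] = _write_csv(
            df, out / "lengths.csv", index=False)

    @stage("similarity")
    def _similarity():
        arts = {}
        metrics = list(config.metrics)
        if embedding_backend is not None and "embed_f1" not in metrics:
            metrics.append("embed_f1")
        for metric in metrics:
            if metric == "embed_f1" and embedding_backend is None:
                manifest["skipped"].append(
                    "similarity/embed_f1: no embedding backend injected")
                continue
            mat = pairwise_matrix(corpus, metric, backend=embedding_backend)
            name = f"matrix_{metric}.csv"
            mat.to_dataframe().to_csv(out / name)
            entry = {"matrix": name, "polarity": mat.polarity,
                     "distance_conversion": ("native" if mat.polarity == "distance"
                                             else "1 - score")}
            if len(corpus) >= 2:
                cl = WardClusterer(n_clusters=config.n_clusters).fit(mat)
                (out / f"dendrogram_{metric}.nwk").write_text(
                    cl.to_newick(), encoding="utf-8")
                entry["dendrogram_newick"] = f"dendrogram_{metric}.nwk"
                entry["dendrogram_json"] = _write_json(
                    cl.to_dict(), out / f"dendrogram_{metric}.json")
                entry["flat_labels"] = {
                    nid: int(lab) for nid, lab in zip(cl.note_ids_, cl.labels_)}
            arts[metric] = entry
        manifest["artifacts"]["similarity"] = arts

    @stage("edit_summaries")
    def _edits():
        if not multi_group:
            manifest["skipped"].append("edit_summaries: fewer than two groups")
            return
        rows = [dataclasses.asdict(s) for s in all_group_edit_summaries(corpus)]
        manifest["artifacts"]["edit_summaries"] = _write_csv(
            pd.DataFrame(rows), out / "edit_summaries.csv", index=False)

    @stage("tfidf_profiles")
    def _tfidf():
        prof = GroupTfidfProfiler(variant=config.tfidf_variant).fit(corpus)
        rows = []
        for g, p in prof.profiles(corpus, k=config.top_k_terms).items():
            for rank, (term, score) in enumerate(p.top_k, 1):
                rows.append({"group": g, "rank": rank, "term": term,
                             "mean_tfidf": score,
                             "variant": config.tfidf_variant})
        manifest["artifacts"]["tfidf_profiles"] = _write_csv(
            pd.DataFrame(rows), out / "tfidf_profiles.csv", index=False)

    @stage("topics")
    def _topics():
        model = GroupTopicModel(n_topics=config.n_topics,
                                seed=config.topic_seed).fit(corpus)
        means = model.group_means(corpus)
        top = {f"topic_{k}": model.top_words(k, 10)
               for k in range(config.n_topics)}
        manifest["artifacts"]["topics"] = {
            "group_means": _write_csv(means, out / "topic_group_means.csv"),
            "top_words": _write_json(top, out / "topic_top_words.json"),
        }

    @stage("variant_entropy")
    def _variants():
        if dictionary is None:
            manifest["skipped"].append("variant_entropy: no variant dictionary supplied")
            return
        concepts = config.variant_concepts or tuple(dictionary.concepts)
        tables = [group_entropy_table(corpus, dictionary, c) for c in concepts]
        manifest["artifacts"]["variant_entropy"] = _write_csv(
            pd.concat(tables, ignore_index=True),
            out / "variant_entropy.csv", index=False)

    @stage("redundancy")
    def _redundancy():
        per_note = RedundancyProfiler(config.compressor_level).fit_transform(corpus)
        agg = group_redundancy(corpus, config.compressor_level)
        manifest["artifacts"]["redundancy"] = {
            "per_note": _write_csv(per_note, out / "redundancy_per_note.csv"),
            "per_group": _write_csv(agg, out / "redundancy_per_group.csv",
                                    index=False),
        }

    @stage("stats")
    def _stats():
        if not multi_group:
            manifest["skipped"].append("stats: fewer than two groups")
            return
        df = length_test_table(corpus, unit=config.length_unit)
        manifest["artifacts"]["stats"] = _write_csv(
            df, out / "length_tests.csv", index=False)

    @stage("bootstrap")
    def _bootstrap():
        if not multi_group:
            manifest["skipped"].append("bootstrap: fewer than two groups")
            return
        groups = corpus.groups()
        sizes = {g: len(ns) for g, ns in groups.items()}
        small = min(sizes, key=sizes.get)
        results = []
        for g, notes in groups.items():
            if g == small or len(notes) <= config.bootstrap_n_target:
                continue
            ref = [note_length(n, config.length_unit) for n in notes]
            obs = float(np.mean(
                [note_length(n, config.length_unit) for n in groups[small]]))
            res = bootstrap_downsample(
                ref, obs, n_target=config.bootstrap_n_target,
                B=config.bootstrap_B, seed=config.bootstrap_seed,
                metric_name=f"length[{config.length_unit}]:{small} vs {g}")
            results.append(dataclasses.asdict(res))
        if results:
            manifest["artifacts"]["bootstrap"] = _write_json(
                results, out / "bootstrap_sensitivity.json")
        else:
            manifest["skipped"].append(
                "bootstrap: no group larger than n_target to downsample")

    _write_json(manifest, out / "manifest.json")
    return manifest


def render_report(manifest_path: str | Path) -> str:
    """Human-readable markdown summary of an analysis bundle."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as e:
        raise ValueError(f"cannot read manifest {manifest_path}: {e}") from e
    out = manifest_path.parent
    lines = ["# notestyle analysis report", "",
             f"- config hash: `{manifest.get('config_hash', '?')}`",
             f"- notes: {manifest.get('n_notes', '?')} "
             f"in groups {manifest.get('groups', {})}", ""]
    arts = manifest.get("artifacts", {})

    def resolve(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(
                f"manifest references missing artifact: {p}")
        return p

    if "lengths" in arts:
        lines += ["## Note lengths", "",
                  pd.read_csv(resolve(arts["lengths"])).to_string(index=False), ""]
    if "stats" in arts:
        lines += ["## Length tests (ANOVA, pairwise Mann-Whitney + Cliff delta, BH)", "",
                  pd.read_csv(resolve(arts["stats"])).to_string(index=False), ""]
    if "edit_summaries" in arts:
        df = pd.read_csv(resolve(arts["edit_summaries"]))
        sym = df[df["direction"] == "symmetrized"]
        lines += ["## Edit-operation summaries (symmetrized)", "",
                  sym.to_string(index=False), ""]
    if "redundancy" in arts:
        df = pd.read_csv(resolve(arts["redundancy"]["per_group"]))
        lines += ["## Redundancy (group means)", "",
                  df.pivot(index="group", columns="metric",
                           values="mean").to_string(), ""]
    if "variant_entropy" in arts:
        lines += ["## Variant entropy", "",
                  pd.read_csv(resolve(arts["variant_entropy"])).to_string(index=False), ""]
    if "topics" in arts:
        lines += ["## Topic profile (group means)", "",
                  pd.read_csv(resolve(arts["topics"]["group_means"]),
                              index_col=0).to_string(), ""]
    if manifest.get("skipped"):
        lines += ["## Skipped stages", ""] + \
                 [f"- {s}" for s in manifest["skipped"]] + [""]
    return "\n".join(lines)
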