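"""End-to-end pipeline: discovery -> filter -> cluster -> screen -> type.

One call runs per-set motif discovery and filtering, pools the surviving
motifs across homolog families, clusters them, removes small clusters,
screens each cluster against its shared motif, types the retained
clusters by their conservation profile and writes a type census — plus a
JSON manifest (config, seeds, input checksums) from which the whole run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import conservation as _conservation
from . import discovery as _discovery
from . import sequence_io as _io
from .matrix import information_content

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter in one reproducible document.

    Defaults are the pipeline's standard operating point: widths 15-25,
    three motifs per set, palindrome constraint on, >= 50 sites and
    >= 75% coverage to survive filtering, clusters of >= 5 members,
    scan threshold 5e-5 single-strand, 200 bp upstream regions.
    """

    min_width: int = 15
    max_width: int = 25
    n_motifs: int = 3
    palindrome: bool = True
    n_starts: int = 5
    max_em_iters: int = 200
    em_tol: float = 1e-4
    min_sites: int = 50
    min_coverage: float = 0.75
    min_mean_ic: float = 0.5
    cutoff: float = 0.15
    min_members: int = 5
    match_thresh: float | None = None  # defaults to the clustering cutoff
    min_overlap: int = 5
    length_penalty: float = 0.5
    high_thresh: float = 1.0
    low_thresh: float = 0.5
    min_run: int = 2
    scan_thresh: float = 5e-5
    norc: bool = True
    upstream_length: int = 200
    seed: int = 0
    run_id: str = "run"

    @property
    def effective_match_thresh(self) -> float:
        return self.cutoff if self.match_thresh is None else self.match_thresh

    def discovery_config(self, seed: int) -> _discovery.DiscoveryConfig:
        return _discovery.DiscoveryConfig(
            min_width=self.min_width, max_width=self.max_width,
            n_motifs=self.n_motifs, palindrome=self.palindrome,
            n_starts=self.n_starts, max_em_iters=self.max_em_iters,
            em_tol=self.em_tol, seed=seed,
        )


def _checksum(upstream: _io.UpstreamSet) -> str:
    h = hashlib.sha256()
    for rec in upstream:
        h.update(f"{rec.gene_id}\t{rec.sequence}\n".encode())
    return h.hexdigest()


def run_pipeline(
    upstream_sets: list[_io.UpstreamSet],
    config: PipelineConfig,
    outdir,
) -> Path:
    """Run every stage and write all outputs under ``outdir``.

    Raises ValueError (naming the stage and input) on stage failures;
    returns the output directory path.
    """
    if not upstream_sets:
        raise ValueError("run_pipeline: no upstream sets given")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "run_id": config.run_id,
        "config": dataclasses.asdict(config),
        "inputs": [
            {"name": s.name, "n_sequences": len(s), "sha256": _checksum(s)}
            for s in upstream_sets
        ],
    }

    # per-set discovery + filtering
    all_motifs: list[_io.MotifRecord] = []
    summaries = []
    for idx, upstream in enumerate(upstream_sets):
        seed = (config.seed * 1009 + idx) % (2**31)
        try:
            results = _discovery.MotifDiscoveryModel(
                upstream, config.discovery_config(seed)
            ).fit()
        except ValueError as exc:
            raise ValueError(
                f"discovery failed on set {upstream.name or idx}: {exc}"
            ) from exc
        kept = _discovery.filter_motifs(
            results.motifs, config.min_sites, config.min_coverage, config.min_mean_ic
        )
        for m in kept:
            m.id = f"set{idx}_{m.id}"
            all_motifs.append(m)
        summary = results.summary()
        summary.insert(0, "set", upstream.name or str(idx))
        summaries.append(summary)

    _io.write_meme_minimal(all_motifs, outdir / "motifs_filtered.meme")
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(
            outdir / "discovery_summary.tsv", sep="\t", index=False
        )

    # pooled clustering + screening + typing
    if len(all_motifs) >= 2:
        cset = _cluster.cluster_motifs(
            all_motifs, cutoff=config.cutoff, min_members=config.min_members,
            min_overlap=config.min_overlap, length_penalty=config.length_penalty,
        )
        _cluster.screen_clusters(
            cset, all_motifs, config.effective_match_thresh,
            config.min_overlap, config.length_penalty,
        )
        for c in cset.clusters:
            c.motif_type = _conservation.classify_profile(
                information_content(c.shared_motif.matrix),
                config.high_thresh, config.low_thresh, config.min_run,
            )
        _cluster.cluster_table(cset).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        _io.write_meme_minimal(
            [c.shared_motif for c in cset.clusters], outdir / "shared_motifs.meme"
        )
        (outdir / "dendrogram.nwk").write_text(cset.to_newick() + "\n")
        type_rows = []
        for c in cset.clusters:
            labeling = _conservation.label_segments(
                information_content(c.shared_motif.matrix),
                config.high_thresh, config.low_thresh, config.min_run,
            )
            peaks, valleys = _conservation.count_peaks_valleys(labeling)
            type_rows.append(
                {"cluster_id": c.id, "type": c.motif_type.name,
                 "n_peaks": peaks, "n_valleys": valleys, "retained": c.retained}
            )
        pd.DataFrame(
            type_rows, columns=["cluster_id", "type", "n_peaks", "n_valleys", "retained"]
        ).to_csv(outdir / "types.tsv", sep="\t", index=False)
        retained = cset.retained_clusters
        census = _conservation.type_census(retained) if retained else \
            _conservation.type_census([])
        census.to_csv(outdir / "census.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["n_motifs_filtered"] = len(all_motifs)
        manifest["n_clusters"] = len(cset.clusters)
        manifest["n_clusters_retained"] = len(retained)
    else:
        manifest["n_motifs_filtered"] = len(all_motifs)
        manifest["n_clusters"] = 0
        manifest["n_clusters_retained"] = 0

    (outdir / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
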