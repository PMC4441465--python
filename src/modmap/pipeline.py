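"""End-to-end Molecular Distance Map pipeline.

Orchestrates FASTA -> CGR images -> pairwise DSSIM distance matrix ->
classical MDS map, writing all products (images, distance matrices,
coordinates, diagnostics, a run manifest and a scatter plot) under one
output directory.  The pipeline never mutates its inputs, and a rerun with
the same configuration produces byte-identical distance and coordinate
tables.
"""

from __future__ import annotations

import difflib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cgr import cgr_encode, render_cgr
from .dssim import (
    DistanceMatrix,
    SsimParams,
    pairwise_distances,
    read_distances_tsv,
    write_distances_phylip,
    write_distances_tsv,
)
from .mds import MapConfiguration, classical_mds, evaluate_stress, scale_map
from .sequence_io import SequenceRecord, read_fasta, read_metadata

logger = logging.getLogger("modmap")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: list[str | Path]
    output_dir: str | Path
    metadata: str | Path | None = None
    k: int = 9
    ssim: SsimParams = field(default_factory=SsimParams)
    q: int = 2
    seed: int = 0
    write_images: bool = True
    plot: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")


def _collect_fasta_paths(inputs: list[str | Path]) -> list[Path]:
    paths: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            paths.extend(sorted(q for q in p.iterdir()
                                if q.suffix.lower() in (".fa", ".fasta", ".fna")))
        else:
            paths.append(p)
    if not paths:
        raise ValueError("no FASTA inputs found")
    return paths


def load_sequences(inputs: list[str | Path]) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for path in _collect_fasta_paths(inputs):
        for rec in read_fasta(path):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} across inputs")
            seen.add(rec.id)
            records.append(rec)
    return records


def _plot_map(
    config: MapConfiguration,
    metadata: pd.DataFrame | None,
    path: Path,
) -> None:
    """Scatter of the first two map axes, coloured by metadata group.

    Legend entries list the number of sequences per group in parentheses.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = config.ids
    xy = config.coords[:, :2] if config.q >= 2 else np.column_stack(
        [config.coords[:, 0], np.zeros(config.n)]
    )
    groups = {}
    if metadata is not None:
        lookup = dict(zip(metadata["id"], metadata["group"]))
        for i, sid in enumerate(ids):
            groups.setdefault(lookup.get(sid, "unassigned"), []).append(i)
    else:
        groups["all"] = list(range(len(ids)))

    fig, ax = plt.subplots(figsize=(7, 7))
    cmap = plt.get_cmap("tab10")
    for gi, (group, idx) in enumerate(sorted(groups.items())):
        pts = xy[idx]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=cmap(gi % 10),
                   label=f"{group} ({len(idx)})")
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    title = "Molecular Distance Map"
    if config.stress1 is not None:
        title += f"  (n={config.n}, Stress-1={config.stress1:.2f})"
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_coords_tsv(config: MapConfiguration, path: str | Path) -> None:
    cols = {f"dim{i + 1}": config.coords[:, i] for i in range(config.q)}
    df = pd.DataFrame({"id": config.ids, **cols})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_map(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Products: ``images/`` (optional PGM CGRs), ``distances.tsv``,
    ``distances.phylip``, ``coords.tsv``, ``diagnostics.json``,
    ``manifest.json`` and ``map.png`` (optional).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    logger.info("stage 1/4: reading sequences")
    records = load_sequences(config.inputs)
    if len(records) < 3:
        raise ValueError(f"need at least 3 sequences, got {len(records)}")
    short = [r.id for r in records if len(r) < config.k]
    if short:
        raise ValueError(
            f"sequences shorter than k={config.k}: {short} (stage: sequence loading)"
        )
    metadata = read_metadata(config.metadata) if config.metadata else None

    logger.info("stage 2/4: encoding %d CGR images at k=%d", len(records), config.k)
    images = [cgr_encode(rec, k=config.k) for rec in records]
    if config.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for im in images:
            render_cgr(im, img_dir / f"{im.source_id}.pgm")

    n_pairs = len(images) * (len(images) - 1) // 2
    logger.info("stage 3/4: computing %d pairwise DSSIM distances", n_pairs)

    def _progress(done: int, total: int) -> None:
        logger.debug("pair %d/%d", done, total)

    matrix = pairwise_distances(images, config.ssim, progress=_progress)
    write_distances_tsv(matrix, out / "distances.tsv")
    write_distances_phylip(matrix, out / "distances.phylip")

    logger.info("stage 4/4: classical MDS into %d dimensions", config.q)
    run_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        map_config = evaluate_stress(matrix, classical_mds(matrix, config.q))
        map_config = scale_map(map_config)
        run_warnings = [str(w.message) for w in caught]

    write_coords_tsv(map_config, out / "coords.tsv")
    a, b = map_config.regression
    diagnostics = {
        "eigenvalues": map_config.eigenvalues.tolist(),
        "stress1": map_config.stress1,
        "regression": {"a": a, "b": b},
        "scaling_record": map_config.scaling_record,
    }
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))

    if config.plot:
        _plot_map(map_config, metadata, out / "map.png")

    upper = matrix.upper_triangle()
    manifest = {
        "tool": {"name": "modmap", "version": __version__},
        "config": {
            "inputs": [str(p) for p in config.inputs],
            "metadata": str(config.metadata) if config.metadata else None,
            "k": config.k,
            "ssim": asdict(config.ssim),
            "q": config.q,
            "seed": config.seed,
            "output_dir": str(out),
            "write_images": config.write_images,
            "plot": config.plot,
            "border_handling": "valid (windows fully inside the image)",
        },
        "sequences": [
            {
                "id": rec.id,
                "length": len(rec),
                "skipped_count": rec.skipped_count,
                "occupied_count": im.occupied_count,
            }
            for rec, im in zip(records, images)
        ],
        "matrix": {
            "n": len(matrix),
            "min_distance": float(upper.min()),
            "max_distance": float(upper.max()),
            "mean_distance": matrix.mean_distance(),
        },
        "stress1": map_config.stress1,
        "warnings": run_warnings,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "done: n=%d, mean DSSIM distance %.4f, Stress-1 %.4f",
        len(matrix), manifest["matrix"]["mean_distance"], map_config.stress1,
    )
    return out


def query_distance(matrix_path: str | Path, id_a: str, id_b: str) -> float:
    """Look up one stored pairwise distance (printed to 4 decimals by the CLI)."""
    matrix = read_distances_tsv(matrix_path)
    for sid in (id_a, id_b):
        if sid not in matrix.ids:
            near = difflib.get_close_matches(sid, matrix.ids, n=3)
            hint = f"; close matches: {near}" if near else ""
            raise KeyError(f"unknown sequence id {sid!r}{hint}")
    return matrix.get(id_a, id_b)


def rank_distances(matrix_path: str | Path, sid: str) -> list[tuple[str, float]]:
    """All other ids sorted by ascending distance from ``sid``.

    Ties are broken lexicographically by id, so the ranking is deterministic
    and suitable for re-plotting distance-curve figures.
    """
    matrix = read_distances_tsv(matrix_path)
    if sid not in matrix.ids:
        near = difflib.get_close_matches(sid, matrix.ids, n=3)
        hint = f"; close matches: {near}" if near else ""
        raise KeyError(f"unknown sequence id {sid!r}{hint}")
    i = matrix.ids.index(sid)
    pairs = [
        (other, float(matrix.values[i, j]))
        for j, other in enumerate(matrix.ids)
        if other != sid
    ]
    return sorted(pairs, key=lambda p: (p[1], p[0]))
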