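"""File formats: FASTA, coordinate tables, annotation/label TSVs, contact-map
and checkpoint containers (compressed .npz with JSON manifests)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import ContactMap


# ----------------------------------------------------------------- sequences

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# --------------------------------------------------------------- coordinates

def write_coord_table(coords: np.ndarray, path) -> None:
    """Whitespace-delimited per-residue coordinate table: index x y z."""
    coords = np.asarray(coords)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(coords):
            fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f}\n")


def read_coord_table(path) -> np.ndarray:
    rows = np.loadtxt(str(path), ndmin=2)
    order = np.argsort(rows[:, 0])
    return rows[order, 1:4]


# --------------------------------------------------------------- annotations

def read_annotations_tsv(path) -> pd.DataFrame:
    """TSV with columns protein_id, term_id[, evidence]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    return df


def write_label_space(space, path) -> None:
    space.to_frame().to_csv(path, sep="\t", index=False)


def read_site_profiles(path) -> dict[tuple[str, str], np.ndarray]:
    """Site TSV (protein_id, function_id, comma-separated residue indices)
    -> {(protein, function): index array} (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        idx = np.array([int(v) for v in str(row["residues"]).split(",") if v != ""],
                       dtype=int)
        out[(row["protein_id"], row["function_id"])] = idx
    return out


# --------------------------------------------------------------- contact maps

def write_contact_maps(cmaps: dict[str, ContactMap], path) -> None:
    arrays = {}
    meta = {}
    for pid, cm in cmaps.items():
        arrays[pid] = cm.adjacency
        meta[pid] = {"mode": cm.mode, "threshold": cm.threshold}
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def read_contact_maps(path) -> dict[str, ContactMap]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        return {pid: ContactMap(adjacency=z[pid], mode=meta[pid]["mode"],
                                threshold=meta[pid]["threshold"])
                for pid in meta}


def write_edge_list(cmap: ContactMap, path) -> None:
    np.savetxt(path, cmap.edge_list(), fmt="%d")


# ------------------------------------------------------------------ datasets

def write_dataset(records: list, space, config, outdir) -> None:
    """Write a synthetic dataset: FASTA, per-protein coordinate tables,
    labels TSV, motif TSV, contact maps, and a JSON config manifest."""
    outdir = Path(outdir)
    (outdir / "coords").mkdir(parents=True, exist_ok=True)
    write_fasta({r.id: r.sequence for r in records}, outdir / "sequences.fasta")
    label_rows, motif_rows = [], []
    cmaps = {}
    for r in records:
        write_coord_table(r.coords, outdir / "coords" / f"{r.id}.txt")
        if r.contact_map is not None:
            cmaps[r.id] = r.contact_map
        for j, term in enumerate(space.terms):
            if r.labels[j]:
                label_rows.append((r.id, term))
        for j, idx in r.motif_indices.items():
            motif_rows.append((r.id, space.terms[j],
                               ",".join(str(int(v)) for v in idx)))
    pd.DataFrame(label_rows, columns=["protein_id", "term_id"]).to_csv(
        outdir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(motif_rows, columns=["protein_id", "term_id", "residues"]
                 ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    if cmaps:
        write_contact_maps(cmaps, outdir / "contact_maps.npz")
    write_label_space(space, outdir / "label_space.tsv")
    cfg = dataclasses.asdict(config)
    cfg["motif_library"] = [dataclasses.asdict(m) for m in config.motif_library]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=float)


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model, path, terms: list | None = None,
                    extra: dict | None = None) -> None:
    """Model parameters (.npz) plus a JSON architecture manifest."""
    from .features import VOCAB

    path = Path(path)
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    manifest = {
        "kind": model.kind,
        "n_terms": model.n_terms,
        "config": dataclasses.asdict(model.config),
        "vocab": VOCAB,
        "terms": terms,
        "lm_dim": getattr(model, "lm_dim", None),
    }
    if extra:
        manifest.update(extra)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def load_checkpoint(path):
    """Rebuild a model from ``save_checkpoint`` output; bit-exact."""
    from .model import CNNConfig, CNNModel, GCNConfig, GCNModel

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    if manifest["kind"] == "gcn":
        cfg = GCNConfig(**{**manifest["config"],
                           "channels": tuple(manifest["config"]["channels"])})
        model = GCNModel(manifest["n_terms"], cfg, lm_dim=manifest.get("lm_dim"))
    else:
        cfg = CNNConfig(filter_widths=tuple(manifest["config"]["filter_widths"]),
                        n_filters=manifest["config"]["n_filters"])
        model = CNNModel(manifest["n_terms"], cfg)
    with np.load(path.with_suffix(".npz")) as z:
        for k, t in model.params.items():
            t.data = np.array(z[k], copy=True)
    return model, manifest


# --------------------------------------------------------------- predictions

def write_predictions_tsv(scores: np.ndarray, protein_ids: list, space,
                          path, floor: float = 0.1) -> None:
    """One row per (protein, term) with score above the reporting floor;
    scores above 0.5 are flagged significant."""
    rows = []
    for i, pid in enumerate(protein_ids):
        for j, term in enumerate(space.terms):
            s = float(scores[i, j])
            if s >= floor:
                rows.append((pid, term, space.names.get(term, ""), round(s, 4),
                             int(s > 0.5)))
    pd.DataFrame(rows, columns=["protein_id", "term_id", "term_name", "score",
                                "significant"]).to_csv(path, sep="\t",
                                                       index=False)


def write_saliency(profiles: list, path_json, path_tsv=None) -> None:
    """Per-protein JSON of per-residue grad-CAM scores; optional flat TSV."""
    data: dict = {}
    rows = []
    for p in profiles:
        data.setdefault(p.protein_id, {})[p.term_id] = [
            float(v) for v in p.profile]
        for i, v in enumerate(p.profile):
            rows.append((p.protein_id, p.term_id, i, float(v)))
    with open(path_json, "w") as fh:
        json.dump(data, fh)
    if path_tsv is not None:
        pd.DataFrame(rows, columns=["protein_id", "term_id", "residue_index",
                                    "score"]).to_csv(path_tsv, sep="\t",
                                                     index=False)
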