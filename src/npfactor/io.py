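"""On-disk formats for the pipeline.

Small, human-inspectable tables (phenotypes, atlases, event and nuisance
tables, edge lists) are TSV.  Connectome containers -- one subjects x
edges matrix per (wave, condition) -- are a hierarchical HDF5 file by
default, with a documented directory-of-TSV dialect that round-trips to
the identical in-memory object.  Every container records the node count,
edge count and the edge-enumeration version tag, which are validated on
read.  Run configuration is YAML and round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, PHENOTYPE_COLUMNS, SYMPTOMS
from .fc import EDGE_ENUMERATION, n_edges

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV -> typed table (NA allowed in symptom cells).

    Mandatory columns: subject_id, wave, site, sex, handedness and the
    eight symptom totals.  Missing symptom values stay NaN and the
    subject is excluded only from analyses of that symptom (complete
    cases per analysis).  Column order in the file is irrelevant.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file misses mandatory column(s): {missing}")
    if df.duplicated(subset=["subject_id", "wave"]).any():
        raise ValueError("duplicated (subject_id, wave) rows")
    df["wave"] = df["wave"].astype(int)
    df["site"] = df["site"].astype("category")
    for col in ("sex", "handedness"):
        df[col] = df[col].astype(int)
    for col in SYMPTOMS:
        df[col] = df[col].astype(float)
    return df[list(PHENOTYPE_COLUMNS)]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# connectome containers


def write_connectomes(
    path,
    connectomes: dict[tuple[int, str], pd.DataFrame],
    n_nodes: int,
    dialect: str = "hdf5",
) -> None:
    """Write per-(wave, condition) edge matrices.

    ``dialect="hdf5"``: one hierarchical file with groups
    ``wave{w}/{condition}`` holding datasets ``z`` and ``subject_id``.
    ``dialect="tsv"``: a directory with one TSV per (wave, condition)
    plus a ``meta.json`` carrying node count and enumeration tag.
    """
    expected = n_edges(n_nodes)
    for key, mat in connectomes.items():
        if mat.shape[1] != expected:
            raise ValueError(f"connectome {key}: edge count != {expected}")
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["n_nodes"] = n_nodes
            f.attrs["n_edges"] = expected
            f.attrs["edge_enumeration"] = EDGE_ENUMERATION
            for (wave, cond), mat in connectomes.items():
                grp = f.create_group(f"wave{wave}/{cond}")
                # track_times off so identical runs give identical bytes
                grp.create_dataset(
                    "z", data=mat.to_numpy(dtype=float), track_times=False
                )
                grp.create_dataset(
                    "subject_id",
                    data=np.array([str(s) for s in mat.index], dtype="S"),
                    track_times=False,
                )
    elif dialect == "tsv":
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_nodes": n_nodes,
            "n_edges": expected,
            "edge_enumeration": EDGE_ENUMERATION,
            "tables": [],
        }
        for (wave, cond), mat in connectomes.items():
            name = f"wave{wave}__{cond}.tsv"
            out = mat.copy()
            out.insert(0, "subject_id", [str(s) for s in mat.index])
            out.to_csv(root / name, sep="\t", index=False)
            meta["tables"].append({"wave": int(wave), "condition": cond, "file": name})
        (root / "meta.json").write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_connectomes(path) -> tuple[dict[tuple[int, str], pd.DataFrame], int]:
    """Read a connectome container (either dialect), validating metadata."""
    p = Path(path)
    if p.is_dir():
        meta = json.loads((p / "meta.json").read_text())
        _check_meta(meta["n_nodes"], meta["n_edges"], meta["edge_enumeration"])
        out = {}
        for entry in meta["tables"]:
            df = pd.read_csv(p / entry["file"], sep="\t", dtype={"subject_id": str})
            mat = df.drop(columns="subject_id")
            mat.index = pd.Index(df["subject_id"])
            mat.columns = range(mat.shape[1])
            if mat.shape[1] != meta["n_edges"]:
                raise ValueError(
                    f"{entry['file']}: {mat.shape[1]} edges, expected {meta['n_edges']}"
                )
            out[(int(entry["wave"]), entry["condition"])] = mat.astype(float)
        return out, int(meta["n_nodes"])
    with h5py.File(p, "r") as f:
        nn = int(f.attrs["n_nodes"])
        _check_meta(nn, int(f.attrs["n_edges"]), str(f.attrs["edge_enumeration"]))
        out = {}
        for wname, wgrp in f.items():
            wave = int(wname.removeprefix("wave"))
            for cond, grp in wgrp.items():
                z = grp["z"][()]
                if z.shape[1] != int(f.attrs["n_edges"]):
                    raise ValueError(f"{wname}/{cond}: edge-count mismatch")
                subjects = [s.decode() for s in grp["subject_id"][()]]
                out[(wave, cond)] = pd.DataFrame(z, index=subjects)
        return out, nn


def _check_meta(n_nodes: int, n_edges_stored: int, tag: str) -> None:
    if tag != EDGE_ENUMERATION:
        raise ValueError(f"unknown edge-enumeration tag {tag!r}")
    if n_edges_stored != n_edges(n_nodes):
        raise ValueError(
            f"edge count {n_edges_stored} inconsistent with {n_nodes} nodes"
        )


def read_cohort(phenotype_path, connectome_path) -> CohortTable:
    pheno = read_phenotypes(phenotype_path)
    conn, n_nodes = read_connectomes(connectome_path)
    return CohortTable(phenotypes=pheno, connectomes=conn, n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# truth / reports


def write_truth(truth, path) -> None:
    payload = {
        "planted": {
            cond: {g: [int(e) for e in ids] for g, ids in groups.items()}
            for cond, groups in truth.planted.items()
        },
        "effect_directions": {
            g: list(v["signs"]) for g, v in truth.effect_directions.items()
        },
        "latents": truth.latents.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# run configuration


def save_config(config_dict: dict, path) -> None:
    """Write the resolved stage configuration next to its outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
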