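"""CSV/TSV/GraphML readers and writers for every pipeline artifact.

All pair-keyed files store the canonical order (first < second); readers
canonicalize out-of-order rows with a warning and reject duplicates.
Gamma values round-trip at 6 decimal places.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import Compound, SynergyRecord, make_key

GAMMA_DECIMALS = 6


class MalformedTableError(ValueError):
    pass


# -- compounds --------------------------------------------------------------


def write_compounds(compounds, path) -> None:
    rows = [
        {
            "id": c.id,
            "smiles": c.smiles,
            "log_ic50": "" if not math.isfinite(c.log_ic50) else c.log_ic50,
            "moa": ";".join(sorted(c.moa_labels)),
            "is_active": c.is_active,
            "in_training": c.in_training,
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_compounds(path) -> list:
    df = pd.read_csv(path, dtype={"id": str, "smiles": str, "moa": str})
    required = {"id", "smiles", "log_ic50", "moa", "is_active", "in_training"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedTableError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise MalformedTableError(f"{path}: duplicate compound ids {dupes}")
    out = []
    for _, row in df.iterrows():
        moa = row["moa"]
        labels = frozenset(x for x in str(moa).split(";") if x) if pd.notna(moa) else frozenset()
        out.append(
            Compound(
                id=row["id"],
                smiles=row["smiles"],
                log_ic50=float(row["log_ic50"]) if pd.notna(row["log_ic50"]) else math.nan,
                moa_labels=labels,
                is_active=bool(row["is_active"]),
                in_training=bool(row["in_training"]),
            )
        )
    return out


# -- combination records ----------------------------------------------------


def write_combinations(records, path) -> None:
    rows = []
    for r in records:
        row = {"compound_1": r.key.first, "compound_2": r.key.second}
        reps = [round(g, GAMMA_DECIMALS) for g in r.gamma_replicates]
        for i, g in enumerate(reps, start=1):
            row[f"gamma_rep{i}"] = g
        # mean of the rounded replicates, so a read-back record is self-consistent
        row["gamma_mean"] = round(sum(reps) / len(reps), GAMMA_DECIMALS)
        row["label"] = r.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_combinations(path) -> list:
    df = pd.read_csv(path, dtype={"compound_1": str, "compound_2": str})
    rep_cols = sorted(c for c in df.columns if c.startswith("gamma_rep"))
    if not rep_cols or "compound_1" not in df.columns or "compound_2" not in df.columns:
        raise MalformedTableError(f"{path}: expected compound_1, compound_2 and gamma_rep* columns")
    records, seen = [], {}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        a, b = row.compound_1, row.compound_2
        if a > b:
            warnings.warn(f"{path}:{line}: pair ({a}, {b}) not in canonical order; canonicalized")
        try:
            key = make_key(a, b)
        except ValueError as exc:
            raise MalformedTableError(f"{path}:{line}: {exc}") from exc
        if key in seen:
            raise MalformedTableError(f"{path}: duplicate pair rows for {key} (lines {seen[key]}, {line})")
        seen[key] = line
        gammas = [round(float(getattr(row, c)), GAMMA_DECIMALS) for c in rep_cols]
        records.append(SynergyRecord.from_replicates(key, gammas))
    return records


# -- dose-response matrices -------------------------------------------------


def write_matrices(matrices, path) -> None:
    """Long-format CSV: one row per matrix cell."""
    rows = []
    for m in matrices:
        for i in range(m.response.shape[0]):
            for j in range(m.response.shape[1]):
                rows.append(
                    {
                        "compound_1": m.key.first,
                        "compound_2": m.key.second,
                        "replicate": m.replicate,
                        "row": i,
                        "col": j,
                        "conc_a": m.conc_a[i],
                        "conc_b": m.conc_b[j],
                        "response": round(float(m.response[i, j]), GAMMA_DECIMALS),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrices(path) -> list:
    import numpy as np

    from .doseresponse import DoseResponseMatrix

    df = pd.read_csv(path, dtype={"compound_1": str, "compound_2": str})
    out = []
    for (a, b, rep), grp in df.groupby(["compound_1", "compound_2", "replicate"], sort=True):
        grp = grp.sort_values(["row", "col"])
        n_r, n_c = grp["row"].max() + 1, grp["col"].max() + 1
        resp = grp["response"].to_numpy().reshape(n_r, n_c)
        conc_a = grp.drop_duplicates("row").sort_values("row")["conc_a"].to_numpy()
        conc_b = grp.drop_duplicates("col").sort_values("col")["conc_b"].to_numpy()
        out.append(
            DoseResponseMatrix(key=make_key(a, b), conc_a=conc_a, conc_b=conc_b, response=resp, replicate=int(rep))
        )
    return out


# -- predictions and nominations -------------------------------------------


def write_predictions(prediction_set, path) -> None:
    rows = [
        {"compound_1": k.first, "compound_2": k.second, "score": round(v, GAMMA_DECIMALS)}
        for k, v in sorted(prediction_set.scores.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["model_id"] = prediction_set.model_id
    df.to_csv(path, index=False)


def read_predictions(path, model_id: str = "loaded", kind: str = "classifier_probability"):
    from .models import PredictionSet

    df = pd.read_csv(path, dtype={"compound_1": str, "compound_2": str})
    scores = {make_key(r.compound_1, r.compound_2): float(r.score) for r in df.itertuples(index=False)}
    if len(scores) != len(df):
        raise MalformedTableError(f"{path}: duplicate pair rows")
    return PredictionSet(model_id=model_id, scores=scores, kind=kind)


def write_nominations(nomination_list, path) -> None:
    rows = [
        {
            "rank": e.rank,
            "compound_1": e.key.first,
            "compound_2": e.key.second,
            "score": round(e.score, GAMMA_DECIMALS),
            "tier": e.tier_label,
            "team": nomination_list.team,
        }
        for e in nomination_list.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- MoA network ------------------------------------------------------------


def network_to_graph(network) -> "nx.Graph":
    g = nx.Graph()
    for label, freq in network.nodes.items():
        g.add_node(label, frequency=int(freq))
    for (a, b), freq in network.edges.items():
        if a == b:
            continue  # GraphML self-loops are kept out of the visual export
        g.add_edge(a, b, frequency=int(freq), mean_gamma=float(network.edge_mean_gamma[(a, b)]))
    return g


def write_network_edges(network, path) -> None:
    rows = [
        {
            "moa_1": a,
            "moa_2": b,
            "frequency": freq,
            "mean_gamma": round(network.edge_mean_gamma[(a, b)], GAMMA_DECIMALS),
        }
        for (a, b), freq in sorted(network.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network_graphml(network, path) -> None:
    nx.write_graphml(network_to_graph(network), path)


# -- manifest ---------------------------------------------------------------


def write_manifest(entries: dict, path) -> None:
    """Plain-text key=value manifest."""
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k}={v}\n")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k] = v
    return out
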