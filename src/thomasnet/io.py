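"""Readers and writers for the structured-text config family (BRN, HPN,
zone schemes), state-graph exports (DOT, GraphML) and trace CSV.

All writers are deterministic byte-for-byte for a fixed input: keys are
ordered canonically and floats use a fixed format.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import yaml

from .analysis import ZoneScheme
from .brn import BRN, Entity, Interaction, Parameterization, StateGraph, TotalityError
from .hpn import Arc, HPNModel, Place, Trace, Transition

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class ConfigError(ValueError):
    pass


def _load_yaml(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"{path}: unsupported schema_version {version}")
    return doc


def _dump_yaml(doc: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# BRN config


def brn_from_dict(doc: dict, context: str = "<config>") -> Tuple[BRN, Parameterization]:
    try:
        entities = [
            Entity(name=str(e["name"]), max_level=int(e.get("max_level", 1)))
            for e in doc["entities"]
        ]
        interactions = [
            Interaction(
                source=str(i["source"]),
                target=str(i["target"]),
                sign=str(i["sign"]),
                threshold=int(i.get("threshold", 1)),
            )
            for i in doc.get("interactions", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{context}: malformed entity/interaction entry ({exc})") from exc
    brn = BRN(entities, interactions)
    table = {}
    for row in doc.get("parameters", []):
        try:
            key = (str(row["entity"]), frozenset(str(r) for r in row.get("resources", [])))
            table[key] = int(row["value"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{context}: malformed parameter row {row!r}") from exc
    k = Parameterization(table)
    missing = k.missing_entries(brn)
    if missing:
        detail = "; ".join(f"entity {e!r}, resources {sorted(r)}" for e, r in missing)
        raise TotalityError(f"{context}: missing parameter rows: {detail}")
    k.validate_total(brn)
    return brn, k


def read_brn_config(path: PathLike) -> Tuple[BRN, Parameterization]:
    """Load a BRN plus its total parameterization; missing parameter
    rows are a load-time error listing every absent entry."""
    return brn_from_dict(_load_yaml(path), context=str(path))


def brn_to_dict(brn: BRN, k: Parameterization) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "brn",
        "entities": [{"name": e.name, "max_level": e.max_level} for e in brn.entities],
        "interactions": [
            {"source": i.source, "target": i.target, "sign": i.sign, "threshold": i.threshold}
            for i in sorted(brn.interactions, key=lambda i: (i.source, i.target))
        ],
        "parameters": [
            {"entity": ent, "resources": sorted(res), "value": value}
            for ent, res, value in k.items_canonical()
        ],
    }


def write_brn_config(brn: BRN, k: Parameterization, path: PathLike) -> None:
    _dump_yaml(brn_to_dict(brn, k), path)


# ---------------------------------------------------------------------------
# HPN config


def hpn_from_dict(doc: dict, context: str = "<config>") -> HPNModel:
    try:
        places = [
            Place(
                name=str(p["name"]),
                kind=str(p.get("kind", "continuous")),
                initial_marking=float(p.get("marking", 0.0)),
            )
            for p in doc["places"]
        ]
        transitions = [
            Transition(name=str(t["name"]), rate_constant=float(t.get("rate", 1.0)))
            for t in doc["transitions"]
        ]
        arcs = [
            Arc(
                source=str(a["source"]),
                target=str(a["target"]),
                kind=str(a.get("kind", "normal")),
                weight=float(a.get("weight", 1.0)),
            )
            for a in doc["arcs"]
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{context}: malformed HPN entry ({exc})") from exc
    return HPNModel(
        places=places,
        transitions=transitions,
        arcs=arcs,
        name=str(doc.get("name", "hpn")),
        variant=str(doc.get("variant", "")),
    )


def read_hpn_config(path: PathLike) -> HPNModel:
    return hpn_from_dict(_load_yaml(path), context=str(path))


def hpn_to_dict(model: HPNModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "hpn",
        "name": model.name,
        "variant": model.variant,
        "places": [
            {"name": p.name, "kind": p.kind, "marking": p.initial_marking}
            for p in model.places
        ],
        "transitions": [
            {"name": t.name, "rate": t.rate_constant} for t in model.transitions
        ],
        "arcs": [
            {"source": a.source, "target": a.target, "kind": a.kind, "weight": a.weight}
            for a in model.arcs
        ],
    }


def write_hpn_config(model: HPNModel, path: PathLike) -> None:
    _dump_yaml(hpn_to_dict(model), path)


# ---------------------------------------------------------------------------
# Zone scheme config


def read_zone_scheme(path: PathLike) -> ZoneScheme:
    doc = _load_yaml(path)
    return ZoneScheme.from_config(doc)


# ---------------------------------------------------------------------------
# Packaged case-study data


def packaged_data_path(filename: str) -> Path:
    resource = importlib.resources.files("thomasnet").joinpath("data", filename)
    with importlib.resources.as_file(resource) as p:
        return Path(p)


def load_packaged_yaml(filename: str) -> dict:
    return _load_yaml(packaged_data_path(filename))


def load_packaged_brn(filename: str) -> Tuple[BRN, Parameterization]:
    return brn_from_dict(load_packaged_yaml(filename), context=filename)


def load_packaged_hpn(filename: str) -> HPNModel:
    return hpn_from_dict(load_packaged_yaml(filename), context=filename)


# ---------------------------------------------------------------------------
# State-graph export


def state_label(state: Sequence[int]) -> str:
    return "(" + ",".join(str(v) for v in state) + ")"


def write_state_graph(graph: StateGraph, fmt: str, path: PathLike) -> None:
    """Export ``graph`` as DOT or GraphML with canonical state-tuple
    labels and deterministic node order."""
    fmt = fmt.lower()
    if fmt == "dot":
        lines = ["digraph stategraph {"]
        for s in sorted(graph.states):
            lines.append(f'  "{state_label(s)}";')
        for s in sorted(graph.states):
            for t in graph.adj[s]:
                lines.append(f'  "{state_label(s)}" -> "{state_label(t)}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for s in sorted(graph.states):
            g.add_node(state_label(s))
        for s in sorted(graph.states):
            for t in graph.adj[s]:
                g.add_edge(state_label(s), state_label(t))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown state-graph format {fmt!r} (use 'dot' or 'graphml')")


# ---------------------------------------------------------------------------
# Trace CSV


def write_trace_csv(trace: Trace, path: PathLike) -> None:
    """CSV with header ``time,<place>...``, lossless to 1e-9."""
    frame = trace.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path: PathLike) -> Trace:
    import pandas as pd

    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ConfigError(f"{path}: trace CSV must have a 'time' column")
    series = {c: frame[c].to_numpy() for c in frame.columns if c != "time"}
    return Trace(time=frame["time"].to_numpy(), series=series, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Plotting


def plot_trace(trace: Trace, path: PathLike, title: str = "") -> None:
    """Overlay of all place series over time (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for place in trace.places:
        ax.plot(trace.time, trace[place], label=place)
    ax.set_xlabel("time (arbitrary units)")
    ax.set_ylabel("expression level (tokens)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
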