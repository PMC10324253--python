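"""Readers, writers, identifier matching, and the run report.

Supported formats:

* edge-list TSV: two columns ``node1 node2`` plus an optional third
  ``confidence`` column;
* GraphML (via networkx);
* STRING links dialect: whitespace- or tab-delimited with header columns
  ``protein1 protein2 combined_score``, the score on STRING's native
  0-1000 integer scale, thresholded at >= 800 by default (the conventional
  "combined confidence >= 0.8" high-confidence cut);
* differential-expression tables: delimited text with columns
  ``gene_id log2fc pvalue`` (optional ``significant``);
* GMT gene-set collections;
* YAML/JSON run configuration and a JSON run report.

Gene/protein identifiers are matched by exact string; an optional
two-column mapping table (protein TAB gene) can be applied when loading a
network.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .engine import AmendConfig, PSOSettings, RunTrace
from .network import InteractionNetwork, Module, largest_connected_component

__all__ = [
    "load_network",
    "write_network",
    "load_de_table",
    "load_gene_sets",
    "load_mapping",
    "join_stats_to_network",
    "load_config",
    "write_run_report",
    "write_module",
]


class InputError(ValueError):
    """Malformed or unreadable input file."""


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in {".graphml", ".xml"}:
        return "graphml"
    with open(path) as fh:
        header = fh.readline()
    fields = header.replace(",", " ").split()
    if {"protein1", "protein2", "combined_score"} <= set(fields):
        return "string"
    return "edgelist"


def load_network(
    path,
    fmt: str = "auto",
    score_threshold: float = 800.0,
    mapping: Optional[dict[str, str]] = None,
) -> InteractionNetwork:
    """Load an undirected network, dropping self-loops and duplicate edges.

    ``fmt`` is one of ``auto``, ``edgelist``, ``graphml``, ``string``.  For
    the STRING dialect, only rows with ``combined_score >= score_threshold``
    (native 0-1000 scale) are kept.  ``mapping`` optionally renames node
    identifiers (e.g. protein to gene); unmapped nodes keep their name.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"network file not found: {path}")
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        net_edges = [(u, v) for u, v in g.edges()]
        extra = [n for n in g.nodes if g.degree[n] == 0]
        edges = net_edges
        nodes = extra
    elif fmt in ("edgelist", "string"):
        edges, nodes = [], []
        is_string = fmt == "string"
        score_col = 2  # default STRING column when no header row is present
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                if is_string and lineno == 1 and parts[0] == "protein1":
                    try:
                        score_col = parts.index("combined_score")
                    except ValueError as err:
                        raise InputError(
                            f"{path}:{lineno}: STRING header lacks combined_score"
                        ) from err
                    continue
                if is_string:
                    if len(parts) < 3:
                        raise InputError(f"{path}:{lineno}: expected 3+ columns")
                    try:
                        score = float(parts[score_col])
                    except (ValueError, IndexError) as err:
                        raise InputError(f"{path}:{lineno}: bad combined_score") from err
                    if score < score_threshold:
                        continue
                    edges.append((parts[0], parts[1], score / 1000.0))
                else:
                    if parts[0] in ("node1", "protein1", "source", "gene1"):
                        continue
                    if len(parts) < 2:
                        raise InputError(f"{path}:{lineno}: expected 2+ columns")
                    if len(parts) >= 3:
                        try:
                            edges.append((parts[0], parts[1], float(parts[2])))
                        except ValueError as err:
                            raise InputError(
                                f"{path}:{lineno}: bad confidence value"
                            ) from err
                    else:
                        edges.append((parts[0], parts[1]))
    else:
        raise InputError(f"unknown network format: {fmt!r}")
    if mapping:
        def remap(n):
            return mapping.get(str(n), str(n))
        edges = [(remap(e[0]), remap(e[1]), *e[2:]) for e in edges]
        nodes = [remap(n) for n in nodes]
    net = InteractionNetwork(edges, nodes=nodes)
    if net.n_nodes == 0:
        raise InputError(f"no edges retained from {path}")
    return net


def write_network(net: InteractionNetwork, path, fmt: str = "edgelist") -> None:
    """Write a network as edge-list TSV or GraphML."""
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in net.edge_list():
                conf = net.graph.edges[u, v].get("confidence")
                if conf is None:
                    fh.write(f"{u}\t{v}\n")
                else:
                    fh.write(f"{u}\t{v}\t{conf:g}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for u, v in net.edge_list():
            g.add_edge(u, v, **net.graph.edges[u, v])
        nx.write_graphml(g, path)
    else:
        raise InputError(f"unknown network format: {fmt!r}")


def load_de_table(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Differential-expression table with columns gene_id, log2fc, pvalue."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"DE table not found: {path}")
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"gene_id", "log2fc", "pvalue"}
    if not required <= set(df.columns):
        raise InputError(
            f"{path}: DE table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["gene_id"] = df["gene_id"].astype(str)
    return df


def load_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping source identifiers to gene identifiers."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def load_gene_sets(path) -> dict[str, list[str]]:
    """GMT reader: name TAB description TAB member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


def join_stats_to_network(
    net: InteractionNetwork, stats: pd.DataFrame
) -> tuple[InteractionNetwork, pd.DataFrame]:
    """Restrict the network to genes with statistics, then take the LCC.

    Returns the reduced network and the statistics aligned to it (rows
    restricted to network nodes, in canonical order).
    """
    shared = [v for v in net.nodes if v in stats.index]
    if not shared:
        raise InputError("no network node matches a gene in the statistics table")
    reduced = net.subnetwork(shared) if len(shared) < net.n_nodes else net
    if reduced.n_nodes and not reduced.is_connected():
        reduced = largest_connected_component(reduced)
    aligned = stats.loc[list(reduced.nodes)]
    return reduced, aligned


def load_config(path) -> AmendConfig:
    """AmendConfig from a YAML or JSON file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"{path}: config must be a mapping")
    pso = PSOSettings(**raw.pop("pso", {}))
    if "alpha_grid" in raw:
        raw["alpha_grid"] = tuple(float(a) for a in raw["alpha_grid"])
    if "decay_grid" in raw:
        raw["decay_grid"] = tuple(float(d) for d in raw["decay_grid"])
    try:
        return AmendConfig(pso=pso, **raw)
    except TypeError as err:
        raise InputError(f"{path}: unknown config field ({err})") from err


def _config_dict(config: AmendConfig) -> dict:
    d = asdict(config)
    d["alpha_grid"] = [float(a) for a in config.alpha_grid]
    d["decay_grid"] = [float(x) for x in config.decay_grid]
    d["pso"]["bounds"] = list(config.pso.bounds)
    return d


def write_module(module: Module, out_dir, net: Optional[InteractionNetwork] = None) -> None:
    """Write module node and edge TSVs (and GraphML if the parent is given)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "module_nodes.tsv", "w") as fh:
        fh.write("gene_id\n")
        for v in module.nodes:
            fh.write(v + "\n")
    with open(out_dir / "module_edges.tsv", "w") as fh:
        fh.write("node1\tnode2\n")
        for u, v in module.edges:
            fh.write(f"{u}\t{v}\n")
    if net is not None:
        write_network(net.subnetwork(module.nodes), out_dir / "module.graphml", "graphml")


def write_run_report(
    path,
    config: AmendConfig,
    module: Module,
    trace: RunTrace,
    input_digests: dict,
    evaluation: Optional[dict] = None,
) -> None:
    """JSON report that fully determines reproduction (config + seed + inputs)."""
    report = {
        "software_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "inputs": input_digests,
        "schedule": {"eta0": trace.eta0, "decay": trace.decay},
        "module": {
            "nodes": list(module.nodes),
            "edges": [list(e) for e in module.edges],
            "score": module.score,
            "iteration": module.iteration,
            "alpha": module.alpha,
            "filtering_rate": module.filtering_rate,
        },
        "trace": [
            {
                "iteration": r.iteration,
                "n_nodes": len(r.nodes),
                "n_edges": r.n_edges,
                "score": r.score,
                "alpha": r.alpha,
                "filtering_rate": r.filtering_rate,
                "mean_z": r.mean_z,
                "mean_ccc": r.mean_ccc,
            }
            for r in trace.records
        ],
    }
    if evaluation is not None:
        report["evaluation"] = evaluation
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
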