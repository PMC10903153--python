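"""Plain-text readers and writers for every pipeline format.

All formats are diffable TSV/CSV/newick with documented column contracts:

* counts TSV: first column ``asv_id``, one column per sample (integers);
* metadata TSV: ``sample_id, treatment, day, replicate`` plus optional
  ``fraction, buoyant_density, total_16s_copies``;
* degradation CSV: ``treatment, replicate, day, smx_mg_per_l`` (an optional
  ``phase`` column is written and consumed when present);
* fraction TSV: ``fraction, buoyant_density, total_16s_copies`` plus ASV
  columns, with ``# key=value`` header lines carrying the isotope, the
  sequenced window, and the fraction-order convention;
* newick for trees; TSV for edge lists, node attributes and robustness
  curves.

Every writer round-trips bit-identically through its paired reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountTable, DegradationSeries, GradientFractionSet

__all__ = [
    "write_count_table",
    "read_count_table",
    "write_degradation",
    "read_degradation",
    "write_fraction_table",
    "read_fraction_table",
    "read_tree",
    "write_tree",
    "write_edge_list",
    "write_node_attributes",
]


# ----------------------------------------------------------------------
# count tables
# ----------------------------------------------------------------------

def write_count_table(table: CountTable, counts_path, metadata_path) -> None:
    out = table.counts.copy()
    out.index.name = "asv_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_count_table(counts_path, metadata_path) -> CountTable:
    """Read and validate a counts TSV + metadata TSV pair.

    Raises distinct errors for duplicated sample ids, non-integer or
    negative counts, and samples missing from the metadata.
    """
    with open(counts_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "asv_id":
        raise ValueError(
            f"counts file must have 'asv_id' as its first column, got {header[0]!r}"
        )
    sample_cols = header[1:]
    dup = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
    if dup:
        raise ValueError(f"duplicated sample ids in counts file: {dup}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.columns = sample_cols  # undo pandas' dedup mangling, if any
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers")
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [s for s in counts.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return CountTable(counts.astype(np.int64), metadata)


# ----------------------------------------------------------------------
# degradation series
# ----------------------------------------------------------------------

def write_degradation(series: DegradationSeries, path) -> None:
    cols = ["treatment", "replicate", "day", "smx_mg_per_l", "phase"]
    series.data[cols].to_csv(path, index=False)


def read_degradation(
    path,
    phase_bounds: dict[str, tuple[float, float]],
    dose_mg_per_l: float,
    dosing_days: tuple[float, ...],
) -> DegradationSeries:
    data = pd.read_csv(path)
    if "phase" not in data.columns:
        # assign phases from the bounds; a dosing-day record is ambiguous and
        # is filed under the phase it opens
        def assign(day: float) -> str:
            items = list(phase_bounds.items())
            for i, (name, (a, b)) in enumerate(items):
                if a <= day < b or (i == len(items) - 1 and day <= b):
                    return name
            raise ValueError(f"day {day} outside all phases")

        data["phase"] = data["day"].map(assign)
    return DegradationSeries(
        data=data,
        phase_bounds=phase_bounds,
        dose_mg_per_l=dose_mg_per_l,
        dosing_days=tuple(dosing_days),
    )


# ----------------------------------------------------------------------
# gradient fraction tables
# ----------------------------------------------------------------------

def write_fraction_table(gfs: GradientFractionSet, path) -> None:
    path = Path(path)
    frame = gfs.fractions.copy()
    frame = frame.join(gfs.counts.T)
    with open(path, "w") as fh:
        fh.write(f"# microcosm={gfs.microcosm_id}\n")
        fh.write(f"# isotope={gfs.isotope}\n")
        fh.write(f"# sequenced_window={gfs.sequenced_window[0]}-{gfs.sequenced_window[1]}\n")
        fh.write(f"# order={'heavy_first' if gfs.heavy_first else 'light_first'}\n")
        frame.index.name = "fraction"
        frame.to_csv(fh, sep="\t")


def read_fraction_table(path, heavy_first: bool | None = None) -> GradientFractionSet:
    """Read a fraction TSV; ``heavy_first`` overrides the declared order.

    The file's density column is the ground truth: if the declared (or
    overriding) convention contradicts the densities, that is an error, not
    a silent reconciliation.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="fraction")
    declared = header.get("order", "heavy_first") == "heavy_first"
    if heavy_first is not None and heavy_first != declared:
        raise ValueError(
            f"requested order {'heavy_first' if heavy_first else 'light_first'} "
            f"contradicts the file's declared order"
        )
    w0, w1 = (header.get("sequenced_window", "1-%d" % len(frame))).split("-")
    asv_cols = [c for c in frame.columns if c not in ("buoyant_density", "total_16s_copies")]
    return GradientFractionSet(
        microcosm_id=header.get("microcosm", path.stem),
        isotope=header.get("isotope", "12C"),
        fractions=frame[["buoyant_density", "total_16s_copies"]],
        counts=frame[asv_cols].T.astype(np.int64),
        sequenced_window=(int(w0), int(w1)),
        heavy_first=declared,
    )


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Parse a rooted newick tree; branch lengths required downstream.

    Unrooted input (a root trifurcation) is midpoint-rooted with a warning;
    polytomies below the root are allowed.
    """
    tree = TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        warnings.warn("input tree is unrooted (root trifurcation); midpoint-rooting")
        tree = tree.root_at_midpoint()
    return tree


def write_tree(tree_or_newick, path) -> None:
    if isinstance(tree_or_newick, str):
        Path(path).write_text(tree_or_newick.rstrip("\n") + "\n")
    else:
        tree_or_newick.write(str(path), format="newick")


# ----------------------------------------------------------------------
# network exports
# ----------------------------------------------------------------------

def write_edge_list(net, path) -> None:
    rows = [
        (u, v, d["rho"], d["sign"])
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_attributes(classified: pd.DataFrame, path) -> None:
    out = classified[["module", "degree", "zi", "pi", "role"]].copy()
    out.index.name = "node"
    out.to_csv(path, sep="\t")
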