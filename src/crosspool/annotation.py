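"""Cluster classing and reference-label homology mapping.

Clusters are classed inhibitory or excitatory by comparing mean normalized
expression of Gad1/Gad2 against Slc17a6. Transferred per-cell reference
labels (label transfer itself is upstream input) are cross-tabulated into
a cluster x label proportion matrix; labels that map indiscriminately are
excluded, and every remaining label covering >= 15% of a cluster is an
accepted homology (a cluster may map to several labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["classify_neuron_class", "label_proportion_matrix", "assign_homology",
           "HomologyAssignment", "DEFAULT_EXCLUDED_LABELS", "DEFAULT_MIN_PROP"]

#: reference labels that lack marker genes and map onto many clusters at once
DEFAULT_EXCLUDED_LABELS = (
    "e1:Glut", "i1:Gaba", "i7:Gaba", "i9:Gaba", "i11:Gaba",
    "i13:Gaba", "i12:Gaba", "i15:Gaba", "i39:Gaba",
)
DEFAULT_MIN_PROP = 0.15

INHIBITORY_MARKERS = ("Gad1", "Gad2")
EXCITATORY_MARKER = "Slc17a6"


@dataclass
class HomologyAssignment:
    cluster: str
    proportions: pd.Series  # over reference labels, sums to 1 before exclusion
    accepted: list[str] = field(default_factory=list)
    excluded_applied: tuple[str, ...] = ()

    @property
    def mapped(self) -> bool:
        return bool(self.accepted)


def classify_neuron_class(cluster_mean_expression: pd.Series,
                          aggregate: str = "mean") -> str:
    """'inhibitory' if Gad1/Gad2 beat Slc17a6, 'excitatory' if the reverse.

    ``aggregate`` picks how the two inhibitory markers are combined
    ("mean" or "max"). Exact ties and all-zero markers are 'unassigned'.
    """
    for g in (*INHIBITORY_MARKERS, EXCITATORY_MARKER):
        if g not in cluster_mean_expression.index:
            raise KeyError(f"marker gene {g!r} missing from expression input")
    inh_vals = cluster_mean_expression[list(INHIBITORY_MARKERS)].astype(float)
    inh = inh_vals.mean() if aggregate == "mean" else inh_vals.max()
    exc = float(cluster_mean_expression[EXCITATORY_MARKER])
    if inh == 0 and exc == 0:
        return "unassigned"
    if inh > exc:
        return "inhibitory"
    if inh < exc:
        return "excitatory"
    return "unassigned"


def label_proportion_matrix(cell_metadata: pd.DataFrame,
                            cluster_key: str = "cluster",
                            label_key: str = "transferred_label") -> pd.DataFrame:
    """Row-normalized cluster x reference-label cross-tabulation."""
    for col in (cluster_key, label_key):
        if col not in cell_metadata.columns:
            raise ValueError(f"missing column {col!r}")
    counts = pd.crosstab(cell_metadata[cluster_key], cell_metadata[label_key])
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty cluster in proportion matrix")
    return counts.div(totals, axis=0)


def assign_homology(proportions: pd.DataFrame,
                    excluded_labels=DEFAULT_EXCLUDED_LABELS,
                    min_prop: float = DEFAULT_MIN_PROP,
                    cluster_class: pd.Series | None = None,
                    label_class=None) -> list[HomologyAssignment]:
    """Accept every (cluster, label) pair with proportion >= ``min_prop``.

    Excluded labels are dropped before thresholding. When ``cluster_class``
    and a ``label_class`` callable (label -> class) are given, the input is
    validated: labels of one class must only occur on clusters of the same
    class (transfer is class-restricted upstream).
    """
    if cluster_class is not None and label_class is not None:
        for clu in proportions.index:
            present = proportions.loc[clu]
            bad = [lab for lab in present.index[present > 0]
                   if label_class(lab) != cluster_class[clu]]
            if bad:
                raise ValueError(
                    f"cluster {clu!r} ({cluster_class[clu]}) carries labels of "
                    f"the other class: {bad}")
    keep_cols = [c for c in proportions.columns if c not in set(excluded_labels)]
    out = []
    for clu in proportions.index:
        props = proportions.loc[clu]
        accepted = [lab for lab in keep_cols if props[lab] >= min_prop]
        out.append(HomologyAssignment(
            cluster=str(clu), proportions=props, accepted=accepted,
            excluded_applied=tuple(excluded_labels)))
    return out


def homology_table(assignments: list[HomologyAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        if a.accepted:
            for lab in a.accepted:
                rows.append({"cluster": a.cluster, "label": lab,
                             "proportion": float(a.proportions[lab])})
        else:
            rows.append({"cluster": a.cluster, "label": "unmapped",
                         "proportion": float(a.proportions.max())})
    return pd.DataFrame(rows, columns=["cluster", "label", "proportion"])
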