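"""Step-wise rule-based classification of hormone-responsive genes.

Genes induced by the hormone contrast (SA = UP) are sorted into clusters
A and B, repressed genes (SA = DOWN) into clusters C and D, from their
calls on a PI-PLC inhibitor contrast, the basal W30 contrast (W30B) and
the W30-under-SA contrast (W30SA).  The rules are applied sequentially
(mirroring the published walk-through) so A/B and C/D are disjoint by
construction.  Running the assignment with two different inhibitors and
intersecting/uniting per-cluster membership gives the *stringent* and
*loose* reconciled clusters.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tricall.calls import DOWN, LEVELS, LEVEL_NAMES, NC, UP, CallTable
from tricall.contingency import modifier_overrepresentation

CLUSTERS = ("A", "B", "C", "D")
#: Variant (near-miss) labels: satisfied all conditions of B (resp. C)
#: except one of the two basal-inhibition requirements.
VARIANTS = ("B^X", "B^W30", "C^X", "C^W30")


class ClusterConfigError(ValueError):
    """Missing contrasts or incompatible assignments."""


@dataclasses.dataclass
class ClusterAssignment:
    """Per-gene cluster labels for one inhibitor analysis.

    ``labels`` maps every universe gene to "A"/"B"/"C"/"D"/"none";
    ``variant_labels`` maps genes to the subset of near-miss labels they
    satisfy (only genes labelled "none" carry variants — a gene in B is
    never also B^X or B^W30).  ``audit`` records, per gene, which
    sequential filter step decided its fate.
    """

    inhibitor: str
    labels: dict[str, str]
    variant_labels: dict[str, frozenset[str]]
    audit: dict[str, list[str]]

    def members(self, cluster: str) -> frozenset[str]:
        return frozenset(g for g, lab in self.labels.items() if lab == cluster)

    def variant_members(self, variant: str) -> frozenset[str]:
        return frozenset(
            g for g, vs in self.variant_labels.items() if variant in vs
        )

    def sizes(self) -> dict[str, int]:
        out = {c: len(self.members(c)) for c in CLUSTERS}
        out.update({v: len(self.variant_members(v)) for v in VARIANTS})
        return out


@dataclasses.dataclass
class ReconciledClusters:
    """Intersection (stringent) and union (loose) of two inhibitor analyses."""

    stringent: dict[str, frozenset[str]]
    loose: dict[str, frozenset[str]]
    per_inhibitor: tuple[ClusterAssignment, ClusterAssignment]

    def sizes(self) -> dict[str, dict[str, int]]:
        return {
            "stringent": {c: len(self.stringent[c]) for c in CLUSTERS},
            "loose": {c: len(self.loose[c]) for c in CLUSTERS},
        }

    def shares(self, n_induced: int, n_repressed: int) -> dict[str, dict[str, float]]:
        """Cluster sizes as percentages of the induced/repressed gene counts."""
        def pct(cluster: str, sets: Mapping[str, frozenset[str]]) -> float:
            total = n_induced if cluster in ("A", "B") else n_repressed
            return 100.0 * len(sets[cluster]) / total if total else float("nan")

        return {
            mode: {c: pct(c, sets) for c in CLUSTERS}
            for mode, sets in (("stringent", self.stringent), ("loose", self.loose))
        }


def assign_clusters(
    table: CallTable,
    inhibitor: str,
    *,
    hormone: str = "SA",
    w30_basal: str = "W30B",
    w30_hormone: str = "W30SA",
    d_excludes_inhibitor_up: bool = True,
    c_excludes_w30sa_up: bool = False,
) -> ClusterAssignment:
    """Assign every gene to A/B/C/D/none for one inhibitor contrast.

    Sequential rules over hormone-induced genes (hormone call UP):

    1. discard genes unaffected by inhibitor, W30B and W30SA (all NC);
    2. **A**: W30SA = DOWN (induction blocked by W30), W30B != UP
       (basal regulation not opposite), inhibitor != DOWN;
    3. **B**: inhibitor = UP and W30B = UP (induced independently by both
       basal inhibitions) and W30SA != DOWN.

    Over hormone-repressed genes (hormone call DOWN):

    4. discard genes unaffected by all three treatment contrasts;
    5. **D**: W30SA = UP, W30B != DOWN, and (by the symmetric default)
       inhibitor != UP — switch off via ``d_excludes_inhibitor_up``;
    6. **C**, evaluated on genes not labelled D: inhibitor = DOWN and
       W30B = DOWN (optionally also W30SA != UP via
       ``c_excludes_w30sa_up``).

    Variant labels mark near-misses of B and C among unlabelled genes:
    B^X satisfied B except W30B != UP; B^W30 satisfied B except
    inhibitor != UP; C^X and C^W30 analogously for the repression side.
    """
    required = [hormone, inhibitor, w30_basal, w30_hormone]
    missing = [c for c in required if c not in table.contrast_names]
    if missing:
        raise ClusterConfigError(f"call table lacks required contrasts: {missing}")

    sa = table.column(hormone)
    inh = table.column(inhibitor)
    w30b = table.column(w30_basal)
    w30sa = table.column(w30_hormone)

    labels: dict[str, str] = {}
    variants: dict[str, frozenset[str]] = {}
    audit: dict[str, list[str]] = {}

    for i, gene in enumerate(table.genes):
        trail: list[str] = []
        label = "none"
        var: set[str] = set()
        if sa[i] == UP:
            if inh[i] == NC and w30b[i] == NC and w30sa[i] == NC:
                trail.append("step1:discarded-unaffected")
            else:
                trail.append("step1:kept")
                if w30sa[i] == DOWN and w30b[i] != UP and inh[i] != DOWN:
                    label = "A"
                    trail.append("step2:A")
                elif inh[i] == UP and w30b[i] == UP and w30sa[i] != DOWN:
                    label = "B"
                    trail.append("step3:B")
                else:
                    trail.append("step3:unlabelled")
            if label == "none" and w30sa[i] != DOWN:
                # near-misses of B: exactly one of the two basal inductions
                if inh[i] == UP and w30b[i] != UP:
                    var.add("B^X")
                elif w30b[i] == UP and inh[i] != UP:
                    var.add("B^W30")
        elif sa[i] == DOWN:
            if inh[i] == NC and w30b[i] == NC and w30sa[i] == NC:
                trail.append("step4:discarded-unaffected")
            else:
                trail.append("step4:kept")
                is_d = w30sa[i] == UP and w30b[i] != DOWN
                if is_d and d_excludes_inhibitor_up and inh[i] == UP:
                    is_d = False
                    trail.append("step5:D-excluded-inhibitor-up")
                if is_d:
                    label = "D"
                    trail.append("step5:D")
                else:
                    is_c = inh[i] == DOWN and w30b[i] == DOWN
                    if is_c and c_excludes_w30sa_up and w30sa[i] == UP:
                        is_c = False
                        trail.append("step6:C-excluded-w30sa-up")
                    if is_c:
                        label = "C"
                        trail.append("step6:C")
                    else:
                        trail.append("step6:unlabelled")
            if label == "none":
                if inh[i] == DOWN and w30b[i] != DOWN:
                    var.add("C^X")
                elif w30b[i] == DOWN and inh[i] != DOWN:
                    var.add("C^W30")
        else:
            trail.append("not-hormone-responsive")
        labels[gene] = label
        variants[gene] = frozenset(var)
        audit[gene] = trail

    return ClusterAssignment(
        inhibitor=inhibitor, labels=labels, variant_labels=variants, audit=audit
    )


def reconcile(a1: ClusterAssignment, a2: ClusterAssignment) -> ReconciledClusters:
    """Per-cluster intersection (stringent) and union (loose) of two analyses."""
    u1, u2 = set(a1.labels), set(a2.labels)
    if u1 != u2:
        diff = sorted(u1 ^ u2)
        raise ClusterConfigError(
            f"assignments cover different universes; symmetric difference "
            f"({len(diff)} genes): {diff[:10]}"
        )
    stringent = {c: a1.members(c) & a2.members(c) for c in CLUSTERS}
    loose = {c: a1.members(c) | a2.members(c) for c in CLUSTERS}
    return ReconciledClusters(stringent=stringent, loose=loose,
                              per_inhibitor=(a1, a2))


def cluster_modifier_profile(
    rc: ReconciledClusters, table: CallTable, modifier: str
) -> pd.DataFrame:
    """Observed/expected/fold of each modifier level within each stringent cluster.

    One row per (cluster, level); the expected count is
    ``cluster size * universe level fraction`` and the fold delegates to
    :func:`tricall.contingency.modifier_overrepresentation`.  Empty
    clusters contribute no rows.
    """
    col = table.column(modifier)
    n = table.n_genes
    index = table.gene_index()
    rows = []
    for cluster in CLUSTERS:
        members = rc.stringent[cluster]
        if not members:
            continue
        for level in LEVELS:
            marginal = int((col == level).sum())
            observed = sum(1 for g in members if col[index[g]] == level)
            expected = len(members) * marginal / n
            fold = (
                modifier_overrepresentation(members, table, modifier, level)
                if marginal > 0
                else float("nan")
            )
            rows.append(
                {
                    "cluster": cluster,
                    "level": LEVEL_NAMES[level],
                    "observed": observed,
                    "expected": expected,
                    "fold": fold,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "level", "observed",
                                       "expected", "fold"])


def membership_frame(rc: ReconciledClusters) -> pd.DataFrame:
    """Long-format membership table (gene, cluster, mode, inhibitors)."""
    a1, a2 = rc.per_inhibitor
    rows = []
    for cluster in CLUSTERS:
        for gene in sorted(rc.loose[cluster]):
            inhibs = [a.inhibitor for a in (a1, a2) if a.labels[gene] == cluster]
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "stringent": gene in rc.stringent[cluster],
                    "inhibitors": ",".join(inhibs),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "cluster", "stringent", "inhibitors"])
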