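"""Cross-study signal overlap detection within one phenotype group.

Two notions of overlap, mirroring the curation protocol: *identical* (the
same rsID reported by two or more independent studies) and *proximal*
(signals from different studies within a symmetric +/-100 kb window on the
same chromosome).  Proximal clusters are, by default, connected components of
the cross-study proximity graph, so two signals more than one window apart
may co-cluster through a chain; the reported span makes chained extents
visible.  A pairwise mode emits each qualifying cross-study pair as its own
cluster instead.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .types import (
    OverlapCluster,
    PhenotypeGroup,
    Signal,
    ValidationError,
    WindowSpec,
    normalize_rsid,
)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _require_single_group(signals: Sequence[Signal]) -> None:
    groups = {s.phenotype_group for s in signals}
    if len(groups) > 1:
        raise ValidationError(
            "overlap detection operates within one phenotype group; "
            f"got {sorted(g.value for g in groups)}"
        )


def _sort_key(s: Signal) -> Tuple[str, int, str, str]:
    return (s.chrom, s.pos, s.rsid, s.study_id)


def _make_cluster(cluster_id: int, kind: str, members: List[Signal]) -> OverlapCluster:
    members = sorted(members, key=_sort_key)
    chrom = members[0].chrom
    positions = [m.pos for m in members]
    return OverlapCluster(
        cluster_id=cluster_id,
        kind=kind,
        members=tuple(members),
        n_studies=len({m.study_id for m in members}),
        span=(chrom, min(positions), max(positions)),
    )


def find_identical(signals: Sequence[Signal]) -> List[OverlapCluster]:
    """Clusters of string-identical rsIDs reported by >= 2 distinct studies.

    rsIDs are compared after lowercasing and whitespace stripping; merge
    history is not resolved.  Output is sorted by (chrom, pos) and invariant
    to input order.
    """
    _require_single_group(signals)
    by_rsid: Dict[str, List[Signal]] = defaultdict(list)
    for s in signals:
        by_rsid[normalize_rsid(s.rsid)].append(s)
    clusters = []
    for members in by_rsid.values():
        if len({m.study_id for m in members}) >= 2:
            clusters.append(_make_cluster(0, "identical", members))
    clusters.sort(key=lambda c: c.span)
    return [
        OverlapCluster(i, c.kind, c.members, c.n_studies, c.span)
        for i, c in enumerate(clusters, start=1)
    ]


def find_proximal(
    signals: Sequence[Signal],
    window: WindowSpec = WindowSpec(),
    mode: str = "component",
) -> List[OverlapCluster]:
    """Clusters of cross-study signals within the proximity window.

    A link exists between two signals iff they share a chromosome, come from
    different studies, and |pos1 - pos2| <= half_width (inclusive, 1-based
    coordinates).  In ``mode="component"`` (default) clusters are connected
    components of that graph with >= 2 distinct studies; same-study pairs
    never create a link but same-study signals may join a component through a
    cross-study chain.  In ``mode="pairwise"`` each qualifying cross-study
    pair becomes its own two-member cluster.
    """
    _require_single_group(signals)
    if mode not in {"component", "pairwise"}:
        raise ValueError(f"unknown mode {mode!r}")

    order = sorted(range(len(signals)), key=lambda i: _sort_key(signals[i]))
    uf = _UnionFind(len(signals))
    pairs: List[Tuple[int, int]] = []
    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for i in order:
        by_chrom[signals[i].chrom].append(i)

    for idxs in by_chrom.values():
        # idxs sorted by pos; sliding window keeps this near-linear for
        # sparse catalogs
        for a in range(len(idxs)):
            i = idxs[a]
            for b in range(a + 1, len(idxs)):
                j = idxs[b]
                if signals[j].pos - signals[i].pos > window.half_width:
                    break
                if signals[i].study_id != signals[j].study_id:
                    uf.union(i, j)
                    pairs.append((i, j))

    clusters: List[OverlapCluster] = []
    if mode == "pairwise":
        seen = set()
        for i, j in pairs:
            key = tuple(sorted((_sort_key(signals[i]), _sort_key(signals[j]))))
            if key in seen:
                continue
            seen.add(key)
            clusters.append(_make_cluster(0, "proximal", [signals[i], signals[j]]))
    else:
        comps: Dict[int, List[Signal]] = defaultdict(list)
        for i in range(len(signals)):
            comps[uf.find(i)].append(signals[i])
        for members in comps.values():
            if len({m.study_id for m in members}) >= 2 and len(members) >= 2:
                clusters.append(_make_cluster(0, "proximal", members))

    clusters.sort(key=lambda c: c.span)
    return [
        OverlapCluster(i, c.kind, c.members, c.n_studies, c.span)
        for i, c in enumerate(clusters, start=1)
    ]


def overlap_report(
    clusters: Sequence[OverlapCluster],
    phenotype_groups: Sequence[PhenotypeGroup] = tuple(PhenotypeGroup),
) -> pd.DataFrame:
    """One row per cluster, sorted by (chrom, start); explicit zero rows.

    Phenotype groups with no clusters still get a record stating
    ``0 clusters`` so that "no overlap" is an affirmative output, never an
    absence.
    """
    rows = []
    groups_with_clusters = set()
    for c in sorted(clusters, key=lambda c: c.span):
        group = c.members[0].phenotype_group
        groups_with_clusters.add(group)
        rows.append(
            {
                "phenotype_group": group.value,
                "cluster_id": c.cluster_id,
                "kind": c.kind,
                "chrom": c.span[0],
                "start": c.span[1],
                "end": c.span[2],
                "n_signals": len(c.members),
                "n_studies": c.n_studies,
                "rsids": ",".join(sorted({m.rsid for m in c.members})),
                "studies": ",".join(sorted({m.study_id for m in c.members})),
            }
        )
    for group in phenotype_groups:
        if group not in groups_with_clusters:
            rows.append(
                {
                    "phenotype_group": group.value,
                    "cluster_id": 0,
                    "kind": "none",
                    "chrom": "",
                    "start": 0,
                    "end": 0,
                    "n_signals": 0,
                    "n_studies": 0,
                    "rsids": "",
                    "studies": "0 clusters",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype_group",
            "cluster_id",
            "kind",
            "chrom",
            "start",
            "end",
            "n_signals",
            "n_studies",
            "rsids",
            "studies",
        ],
    )


def clusters_to_bed(clusters: Sequence[OverlapCluster]) -> str:
    """Cluster spans as BED lines (0-based half-open) for browser inspection."""
    lines = []
    for c in sorted(clusters, key=lambda c: c.span):
        chrom, start, end = c.span
        name = f"{c.kind}_{c.cluster_id}"
        lines.append(f"{chrom}\t{start - 1}\t{end}\t{name}\t{c.n_studies}")
    return "\n".join(lines) + ("\n" if lines else "")
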