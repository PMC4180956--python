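"""Readers and writers for the pipeline's file formats.

Inputs: SEG-like segment TSV, SNV TSV or VCF 4.x, and a cluster-level
TSV that bypasses CP estimation and clustering entirely (useful for
reproducing analyses from published cluster tables or external CP
estimators such as PyClone).  Outputs: CP-event TSV, cluster TSV,
solutions JSON (round-trippable), Newick, merged-solutions JSON,
pairwise co-localization TSV and a DOT consensus graph.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cellprev import CPEvent, ParameterError, SegmentMeasurement, SNVMeasurement
from .clustering import ClusterSet, CPCluster, clusters_from_table
from .coloc import CLFMatrix, ColocCall, order_events
from .enumeration import SolutionSet, SubcloneTree
from .merging import MergedSolution, MergedTree

logger = logging.getLogger("subclonetk")

__all__ = [
    "read_segments",
    "read_snvs",
    "read_clusters",
    "read_cluster_sets",
    "write_events",
    "write_clusters",
    "write_solutions",
    "read_solutions",
    "write_merged",
    "write_coloc_table",
    "write_consensus_dot",
]


def read_segments(path) -> List[SegmentMeasurement]:
    """Read a SEG-like TSV: sample, chrom, start, end, log2_ratio[, mbaf].

    Malformed rows are skipped with a logged warning; a file with no
    valid rows is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out, skipped = [], 0
    for _, row in df.iterrows():
        try:
            mbaf = None
            if "mbaf" in df.columns and pd.notna(row["mbaf"]):
                mbaf = float(row["mbaf"])
            out.append(
                SegmentMeasurement(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    log2_ratio=float(row["log2_ratio"]),
                    sample_id=str(row["sample"]),
                    mbaf_mean=mbaf,
                )
            )
        except (ParameterError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping segment row: %s", exc)
    if not out:
        raise ValueError(f"{path}: no valid segment records")
    if skipped:
        logger.warning("%d malformed segment rows skipped", skipped)
    return out


def _zygosity_from_gt(gt) -> str:
    alleles = [a for a in (gt or []) if a is not None]
    return "homozygous" if alleles and all(a == alleles[0] and a > 0 for a in alleles) else "heterozygous"


def _read_vcf(path) -> List[SNVMeasurement]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            if samples:
                for sample in samples:
                    fmt = rec.samples[sample]
                    af = fmt.get("AF")
                    if af is None:
                        af = rec.info.get("AF")
                    if af is None:
                        logger.warning("no AF for %s:%s in %s; skipped", rec.chrom, rec.pos, sample)
                        continue
                    if isinstance(af, (tuple, list)):
                        af = af[0]
                    out.append(
                        SNVMeasurement(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            af=float(af),
                            sample_id=sample,
                            zygosity=_zygosity_from_gt(fmt.get("GT")),
                        )
                    )
            else:
                af = rec.info.get("AF")
                if af is None:
                    continue
                if isinstance(af, (tuple, list)):
                    af = af[0]
                out.append(
                    SNVMeasurement(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        af=float(af), sample_id=Path(str(path)).stem,
                    )
                )
    return out


def read_snvs(path) -> List[SNVMeasurement]:
    """Read somatic SNVs from a VCF (FORMAT AF, then INFO AF) or a TSV
    with columns sample, chrom, pos, ref, alt, af[, zygosity]."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        records = _read_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
        required = {"sample", "chrom", "pos", "ref", "alt", "af"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        records, skipped = [], 0
        for _, row in df.iterrows():
            try:
                records.append(
                    SNVMeasurement(
                        chrom=str(row["chrom"]),
                        pos=int(row["pos"]),
                        ref=str(row["ref"]),
                        alt=str(row["alt"]),
                        af=float(row["af"]),
                        sample_id=str(row["sample"]),
                        zygosity=str(row.get("zygosity", "heterozygous"))
                        if "zygosity" in df.columns and pd.notna(row["zygosity"])
                        else "heterozygous",
                    )
                )
            except (ParameterError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping SNV row: %s", exc)
        if skipped:
            logger.warning("%d malformed SNV rows skipped", skipped)
    if not records:
        raise ValueError(f"{path}: no valid SNV records")
    return records


def read_clusters(path) -> List[CPCluster]:
    """Read a cluster-level TSV (cluster_id, sample, cp) — the bypass input."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "sample": str})
    required = {"cluster_id", "sample", "cp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return clusters_from_table(
        df[["cluster_id", "sample", "cp"]].itertuples(index=False, name=None)
    )


def read_cluster_sets(path, zero_threshold: float = 0.05, tie_epsilon: float = 1e-3):
    """Read a cluster TSV and project it into one ClusterSet per sample."""
    from .clustering import project_cluster_set

    clusters = read_clusters(path)
    samples = sorted({s for c in clusters for s in c.cp_by_sample})
    return {
        s: project_cluster_set(clusters, s, zero_threshold, tie_epsilon) for s in samples
    }


def write_events(events: Sequence[CPEvent], path) -> None:
    pd.DataFrame(
        [(e.event_id, e.sample_id, e.source, e.cp) for e in events],
        columns=["event_id", "sample", "source", "cp"],
    ).to_csv(path, sep="\t", index=False)


def write_clusters(clusters: Sequence[CPCluster], path) -> None:
    rows = []
    for c in clusters:
        for sample, cp in sorted(c.cp_by_sample.items()):
            rows.append(
                (c.cluster_id, sample, cp, len(c.member_event_ids), ";".join(c.member_event_ids))
            )
    pd.DataFrame(
        rows, columns=["cluster_id", "sample", "cp", "n_members", "member_ids"]
    ).to_csv(path, sep="\t", index=False)


def _solution_set_dict(solutions: SolutionSet) -> dict:
    return {
        "sample_id": solutions.sample_id,
        "clusters": [
            {"label": l, "cp": cp}
            for l, cp in zip(solutions.cluster_set.labels, solutions.cluster_set.cps)
        ],
        "stats": {"visited": solutions.visited, "viable": solutions.viable},
        "trees": [t.to_dict() for t in solutions.trees],
    }


def write_solutions(solutions: SolutionSet, path, fmt: str = "json") -> None:
    """Write a solution set as JSON (round-trippable), Newick, or a TSV summary."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_solution_set_dict(solutions), indent=1))
    elif fmt == "newick":
        path.write_text("".join(t.to_newick() + "\n" for t in solutions.trees))
    elif fmt == "tsv-summary":
        pd.DataFrame(
            [
                (i, t.n, t.normal_fraction)
                for i, t in enumerate(solutions.trees)
            ],
            columns=["tree_id", "n_clusters", "normal_fraction"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown solutions format {fmt!r}")


def read_solutions(path) -> SolutionSet:
    d = json.loads(Path(path).read_text())
    labels = tuple(c["label"] for c in d["clusters"])
    cps = tuple(float(c["cp"]) for c in d["clusters"])
    cluster_set = ClusterSet(d["sample_id"], labels, cps)
    trees = [SubcloneTree.from_dict(t) for t in d["trees"]]
    return SolutionSet(d["sample_id"], cluster_set, trees, d["stats"]["visited"])


def write_merged(merged: Sequence[MergedSolution], path, summary_path=None) -> None:
    """Merged-solutions JSON plus an optional per-primary-tree summary TSV."""
    doc = [
        {
            "primary_tree": m.primary_index,
            "relapse_tree": m.relapse_index,
            "merged": m.merged.to_dict(),
            "anchors": {str(k): v for k, v in m.anchors.items()},
        }
        for m in merged
    ]
    Path(path).write_text(json.dumps(doc, indent=1))
    if summary_path is not None:
        counts: Dict[int, int] = {}
        for m in merged:
            counts[m.primary_index] = counts.get(m.primary_index, 0) + 1
        pd.DataFrame(
            sorted(counts.items()),
            columns=["primary_tree_id", "n_compatible_relapse_trees"],
        ).to_csv(summary_path, sep="\t", index=False)


def write_coloc_table(
    clf: CLFMatrix,
    calls: Sequence[ColocCall],
    cluster_set: Optional[ClusterSet],
    path,
) -> None:
    """Pairwise TSV: cluster_a, cluster_b, clf, status, earlier_cluster."""
    rows = []
    for call in calls:
        earlier = ""
        if cluster_set is not None and call.status == "co-localized":
            rel = order_events(call.cluster_a, call.cluster_b, cluster_set, [call])
            earlier = call.cluster_a if rel == "a_first" else call.cluster_b
        rows.append((call.cluster_a, call.cluster_b, call.clf, call.status, earlier))
    pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "clf", "status", "earlier_cluster"]
    ).to_csv(path, sep="\t", index=False)


def write_consensus_dot(relations: Sequence[Tuple[str, str, float]], path) -> None:
    """Consensus lineage relations as a DOT digraph (earlier -> later)."""
    lines = ["digraph consensus {"]
    nodes = sorted({x for rel in relations for x in rel[:2]})
    for nlabel in nodes:
        lines.append(f'  "{nlabel}";')
    for x, y, support in relations:
        lines.append(f'  "{x}" -> "{y}" [label="{support:.2f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
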