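"""Tabular and FASTA writers for panels, hotspot reports, and screen verdicts.

All coordinates in these files are 1-based inclusive except BED output, which
follows the 0-based half-open BED convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from .hotspots import HotspotCluster
from .oligo_design import MixSpec, SpeciesPanel
from .specificity import SpecificityVerdict

__all__ = [
    "write_panel_fasta",
    "write_panel_manifest",
    "write_hotspot_report",
    "write_targets_bed",
    "write_verdicts_tsv",
    "write_mix_tsv",
]


def write_panel_fasta(panel: SpeciesPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in panel.primers:
            fh.write(f">{p.name} kind={p.kind} subunit={p.subunit_id}\n{p.sequence}\n")
        for pr in panel.probes:
            fh.write(
                f">{pr.name} kind=rnaseh_probe subunit={pr.subunit_id}\n"
                f"{pr.sequence}\n"
            )


def write_panel_manifest(
    panel: SpeciesPanel, path: str | Path, header_meta: Mapping | None = None
) -> None:
    """TSV manifest with the design configuration logged in the header."""
    meta = {
        "species": panel.species_id,
        "min_tm_C": panel.design_cfg.min_tm_C,
        "thermo": {
            "model": panel.design_cfg.thermo.model,
            "parameter_set": panel.design_cfg.thermo.parameter_set,
            "monovalent_salt_mM": panel.design_cfg.thermo.monovalent_salt_mM,
            "oligo_conc_nM": panel.design_cfg.thermo.oligo_conc_nM,
        },
        "hotspot": {
            "top_k": panel.hotspot_cfg.top_k,
            "cluster_gap_nt": panel.hotspot_cfg.cluster_gap_nt,
            "max_targets_per_subunit": panel.hotspot_cfg.max_targets_per_subunit,
            "min_cluster_read_fraction": panel.hotspot_cfg.min_cluster_read_fraction,
        },
        **(dict(header_meta) if header_meta else {}),
    }
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta, sort_keys=True)}\n")
        fh.write("name\tsubunit\tkind\tref_start\tref_end\tlength\ttm_C\tsequence\n")
        for p in panel.primers:
            fh.write(
                f"{p.name}\t{p.subunit_id}\t{p.kind}\t{p.ref_start}\t{p.ref_end}\t"
                f"{p.length}\t{p.tm_C:.2f}\t{p.sequence}\n"
            )
        for pr in panel.probes:
            fh.write(
                f"{pr.name}\t{pr.subunit_id}\trnaseh_probe\t{pr.ref_start}\t"
                f"{pr.ref_end}\t{pr.length}\tNA\t{pr.sequence}\n"
            )


def write_hotspot_report(
    clusters_by_subunit: Mapping[str, Sequence[HotspotCluster]],
    selected: Mapping[str, Sequence[int]],
    totals: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "subunit\tcluster\tmembers\ttotal_reads\tread_fraction\ttarget\tselected\n"
        )
        for sub, clusters in clusters_by_subunit.items():
            chosen = set(selected.get(sub, ()))
            for i, cluster in enumerate(clusters, 1):
                frac = cluster.total_reads / totals[sub] if totals[sub] else 0.0
                members = ",".join(str(c) for c in cluster.coordinates)
                fh.write(
                    f"{sub}\t{i}\t{members}\t{cluster.total_reads}\t{frac:.4f}\t"
                    f"{cluster.target}\t{int(cluster.target in chosen)}\n"
                )


def write_targets_bed(
    targets_by_subunit: Mapping[str, Sequence[int]], path: str | Path
) -> None:
    """Hotspot targets as single-base BED intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for sub, targets in targets_by_subunit.items():
            for t in targets:
                fh.write(f"{sub}\t{t - 1}\t{t}\thotspot_target\n")


def write_verdicts_tsv(
    verdicts: Sequence[SpecificityVerdict], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("oligo\tbest_evalue\tlongest_run_nt\tworst_transcript\tpass\n")
        for v in verdicts:
            fh.write(
                f"{v.oligo_name}\t{v.best_evalue:.6g}\t{v.longest_run_nt}\t"
                f"{v.worst_transcript_id}\t{int(v.passed)}\n"
            )


def write_mix_tsv(mix: MixSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit={mix.unit} total={mix.total:.6g} bootstrap={mix.bootstrap}\n")
        for group, total in mix.group_totals.items():
            fh.write(f"# group {group} total={total:.6g}\n")
        fh.write("component\tamount\n")
        for name, amount in mix.components.items():
            fh.write(f"{name}\t{amount:.6g}\n")
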