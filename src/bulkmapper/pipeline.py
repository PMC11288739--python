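"""End-to-end orchestration: map and run the cascade in both directions.

Each bulk is analyzed once as the target with the other as control.  All
stage outputs (ADD tracks, regions, cascade report, candidates) are
written per direction, plus a machine-readable JSON summary with stable
key ordering, so reruns on identical inputs produce byte-identical
summaries.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

import pyfaidx

from . import __version__, variant_io
from .add_mapping import (
    MappingParams,
    build_tracks,
    call_linked_regions,
    control_filter,
    depth_filter,
    running_median,
)
from .cascade import run_cascade
from .effects import protein_change_string

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunSummary:
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2) + "\n"

    def direction(self, bulk: str) -> dict:
        return self.data["directions"][bulk]


def map_bulk(sites, target: str, control: str, params: MappingParams):
    """ADD-map one bulk against its control; returns (tracks, regions).

    SNPs with zero depth in either bulk are excluded up front (ADD is
    undefined at 0/0 and the control filter needs control reads).
    """
    snps = [
        s for s in sites
        if s.is_snp and s.depth(target) >= 1 and s.depth(control) >= 1
    ]
    if not snps:
        return [], []
    kept = depth_filter(snps, target, params)
    kept = control_filter(kept, control, params)
    tracks = [running_median(t, params) for t in build_tracks(kept, target)]
    regions = [r for t in tracks for r in call_linked_regions(t, params)]
    return tracks, regions


def run_full(
    vcf: str,
    gff: str,
    fasta: str,
    bulk_a: str,
    bulk_b: str,
    params: Optional[MappingParams] = None,
    out_dir: Optional[str] = None,
    min_alt_fraction: float = 0.9,
    min_depth: int = 5,
    seed: Optional[int] = None,
) -> RunSummary:
    """Run mapping + cascade with each bulk as target and the other as control.

    Fails fast: any stage error removes the partial outputs of this run and
    raises :class:`PipelineError` naming the stage.
    """
    params = params or MappingParams()
    written: List[str] = []

    def _out(name: str) -> str:
        path = os.path.join(out_dir, name)
        written.append(path)
        return path

    stage = "read_inputs"
    try:
        stats: Dict[str, int] = {}
        sites = variant_io.read_biallelic_sites(vcf, (bulk_a, bulk_b), stats)
        genes = variant_io.read_gene_models(gff)
        genome = pyfaidx.Fasta(fasta)
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)

        directions = {}
        for target, control in ((bulk_a, bulk_b), (bulk_b, bulk_a)):
            stage = f"map[{target}]"
            tracks, regions = map_bulk(sites, target, control, params)
            stage = f"cascade[{target}]"
            report = run_cascade(
                sites, sites, target, control, regions, genes, genome,
                min_alt_fraction=min_alt_fraction, min_depth=min_depth,
            )
            stage = f"write[{target}]"
            if out_dir:
                variant_io.write_add_track(tracks, _out(f"{target}.add_track.tsv"))
                variant_io.write_regions(regions, _out(f"{target}.regions.tsv"))
                variant_io.write_cascade_report(report, _out(f"{target}.cascade.tsv"))
                variant_io.write_candidates(report, _out(f"{target}.candidates.tsv"))
            directions[target] = {
                "control": control,
                "regions": [
                    {
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "n_snps": r.n_snps,
                        "median_add": round(r.median_add, 6),
                    }
                    for r in regions
                ],
                "cascade": [
                    {
                        "level": lv.name,
                        "allele_count": lv.allele_count,
                        "gene_count": lv.gene_count,
                    }
                    for lv in report.levels
                ],
                "candidates": [
                    {
                        "chrom": c.site.chrom,
                        "pos": c.site.pos,
                        "ref": c.site.ref_allele,
                        "alt": c.site.alt_allele,
                        "gene_id": c.gene_id,
                        "effect": c.effect.category.value,
                        "protein_change": (
                            protein_change_string(c.effect)
                            if c.effect.protein_pos is not None
                            else ""
                        ),
                    }
                    for c in report.candidates
                ],
            }

        stage = "summary"
        summary = RunSummary(
            data={
                "tool": "bulkmapper",
                "version": __version__,
                "seed": seed,
                "inputs": {"vcf_records": stats.get("n_records", 0)},
                "parameters": {
                    "depth_sd_multiplier": params.depth_sd_multiplier,
                    "control_add_max": params.control_add_max,
                    "window_k": params.window_k,
                    "region_threshold": params.region_threshold,
                    "min_alt_fraction": min_alt_fraction,
                    "min_depth": min_depth,
                },
                "directions": directions,
            }
        )
        if out_dir:
            with open(_out("run_summary.json"), "w") as fh:
                fh.write(summary.to_json())
        return summary
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
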