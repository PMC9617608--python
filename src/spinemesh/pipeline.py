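"""End-to-end analysis pipeline: volume + mask -> statistics bundle.

Stages: cytosol masking, Gaussian denoising, local-threshold
binarization, distance-transform thinning, stub pruning, graph
construction, then the full battery of morphometrics (branch lengths and
tortuosity, node ranks and densities, membrane-relative orientations,
spatial profiles, elementary loops, MST pruning, volume fractions, neck
width, branch-end clustering).  Deterministic for a fixed
``config.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .graph import SkeletonGraph, build_graph
from .loops import loop_statistics, merge_rank2_nodes, minimum_spanning_tree_prune, prune_stats
from .segmentation import (
    gaussian_smooth,
    local_threshold_binarize,
    mask_intracellular,
    segmentation_correlation,
)
from .skeletonize import skeletonize_binary
from .spatial import (
    boundary_distance_field,
    branch_orientation,
    cytoskeleton_volume_fraction,
    neck_width_estimate,
    profile_vs_distance,
)
from .topology import branch_end_clustering_test, branching_angles_rank3, node_density, node_rank_distribution
from .volume import DOMAIN_NAMES, LabelMask, VolumeGrid


@dataclass
class ReportBundle:
    """All per-spine tables produced by one pipeline run."""

    graph: SkeletonGraph
    pruned_graph: SkeletonGraph
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import export_graph

        export_graph(self.graph, outdir / "graph", format="csv-tables")
        for name, df in sorted(self.tables.items()):
            df.to_csv(outdir / f"{name}.csv", index=False)
        pd.DataFrame(
            sorted(self.scalars.items()), columns=["quantity", "value"]
        ).to_csv(outdir / "scalars.csv", index=False)


def run_pipeline(
    config: AnalysisConfig, volume: VolumeGrid, mask: LabelMask
) -> ReportBundle:
    """Run the full analysis on one volume/mask pair."""
    mask.check_companion(volume)
    if not mask.cytosol().any():
        raise ValueError("mask contains no cytosol voxels: nothing to analyze")

    masked = mask_intracellular(volume, mask)
    smoothed = gaussian_smooth(masked, config.sigma_smooth, mask)
    binar = local_threshold_binarize(
        smoothed,
        window_size=config.window_size,
        k=config.k,
        mask=mask,
        threshold_form=config.threshold_form,
    )
    if not binar.foreground.any():
        raise ValueError("binarization produced an empty foreground")
    skel = skeletonize_binary(binar, stub_min=config.stub_min)
    graph = build_graph(skel, mask)
    dfield = boundary_distance_field(mask)

    tables: dict[str, pd.DataFrame] = {}
    scalars: dict[str, float] = {}

    scalars["foreground_fraction"] = binar.foreground_fraction(mask)
    scalars["pearson_r"] = segmentation_correlation(smoothed, binar, mask)

    # branch geometry per domain
    rows = []
    for b in graph.included_branches():
        if b.tortuosity is None:
            continue
        rows.append(
            dict(
                branch_id=b.id,
                domain=DOMAIN_NAMES.get(b.domain, str(b.domain)),
                length_nm=b.arc_length,
                tortuosity=b.tortuosity,
                orientation_deg=branch_orientation(b, dfield),
                dt_nm=float(dfield.dt_at(b.com.reshape(1, 3))[0]),
            )
        )
    tables["branches_stats"] = pd.DataFrame(rows)

    tables["node_ranks"] = node_rank_distribution(graph)
    dens = node_density(graph, mask)
    for dom, v in dens.items():
        scalars[f"node_density_per_um3_{dom}"] = v
    vf = cytoskeleton_volume_fraction(graph, mask, config.sigma_vol)
    for dom, v in vf.items():
        scalars[f"cytoskeleton_volume_fraction_{dom}"] = v

    # spatial profiles
    bdf = tables["branches_stats"]
    if len(bdf):
        coms = np.array([graph.branches[i].com for i in bdf.branch_id])
        tables["tortuosity_profile"] = profile_vs_distance(
            coms, bdf.tortuosity.to_numpy(), dfield, bin_width=config.profile_bin
        )
        tables["orientation_profile"] = profile_vs_distance(
            coms, bdf.orientation_deg.to_numpy(), dfield, bin_width=config.profile_bin
        )
    junc_pos = np.array(
        [n.position for n in graph.junction_nodes()]
    ).reshape(-1, 3)
    if len(junc_pos):
        tables["node_density_profile"] = profile_vs_distance(
            junc_pos, None, dfield, bin_width=config.profile_bin, mask=mask
        )
    end_pos = np.array([n.position for n in graph.rank1_nodes()]).reshape(-1, 3)
    if len(end_pos):
        tables["end_density_profile"] = profile_vs_distance(
            end_pos, None, dfield, bin_width=config.profile_bin, mask=mask
        )

    # branching angles
    triples = branching_angles_rank3(graph)
    tables["branching_angles"] = pd.DataFrame(
        [
            dict(
                node_id=t.node_id,
                smallest=t.angles[0],
                intermediate=t.angles[1],
                largest=t.angles[2],
                angle_sum=t.angle_sum,
            )
            for t in triples
        ]
    )

    # branch-end clustering near the membrane
    clu = branch_end_clustering_test(
        graph, dfield, shell=config.shell_width, seed=config.rng_seed, n_rand=100
    )
    if clu is not None:
        scalars["end_nn_observed_nm"], scalars["end_nn_random_nm"], scalars[
            "end_nn_pvalue"
        ] = clu

    # loops and spanning trees
    loops = loop_statistics(graph)
    for key, v in loops.items():
        scalars[f"loops_{key}"] = v
    pruned = minimum_spanning_tree_prune(graph)
    ps = prune_stats(graph, pruned, mask, config.sigma_vol)
    for key, v in ps.items():
        scalars[f"mst_{key}"] = v
    pruned_merged = merge_rank2_nodes(pruned)

    nw = neck_width_estimate(mask, dfield)
    if nw is not None:
        scalars["neck_width_nm"] = nw

    return ReportBundle(
        graph=graph, pruned_graph=pruned_merged, tables=tables, scalars=scalars
    )
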