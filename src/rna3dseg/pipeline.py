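"""End-to-end segmentation: trace → Mean Shift → rule refinement."""

from __future__ import annotations

import logging

from .core import ChainTrace, DomainDecomposition
from .meanshift import ClusterLabeling, MeanShiftConfig, mean_shift_cluster
from .postcluster import Thresholds, refine_decomposition

logger = logging.getLogger(__name__)

#: Chains shorter than this cannot host a domain and are refused.
MIN_CHAIN_LENGTH = 30


def segment_trace(trace: ChainTrace,
                  config: MeanShiftConfig | None = None,
                  thresholds: Thresholds | None = None,
                  postprocess: bool = True,
                  ) -> tuple[DomainDecomposition, ClusterLabeling]:
    """Segment one chain trace into domains and linkers.

    Returns the final decomposition together with the raw clustering (for
    inspection of the pre-refinement state).  With ``postprocess=False`` the
    decomposition is built directly from the raw labels: every maximal run
    of one cluster label becomes a domain segment and outlier runs become
    linkers, with no rule applied.
    """
    thresholds = thresholds or Thresholds()
    if len(trace) < MIN_CHAIN_LENGTH:
        raise ValueError(f"chain has {len(trace)} residues, below the "
                         f"{MIN_CHAIN_LENGTH}-nt minimum for a 3D domain")
    labeling = mean_shift_cluster(trace.coords, config)
    if postprocess:
        decomposition = refine_decomposition(labeling.labels, thresholds)
    else:
        from .postcluster import decomposition_from_segments, segments_from_labels
        decomposition = decomposition_from_segments(
            segments_from_labels(labeling.labels))
    logger.info("chain %s: %d nt, bandwidth %.2f Å, %d clusters raw, "
                "%d domains after refinement",
                trace.chain_id, len(trace), labeling.bandwidth,
                labeling.n_clusters, len(decomposition.domains))
    return decomposition, labeling
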