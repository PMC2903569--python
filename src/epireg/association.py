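"""Stage (ii): pair representative methylation profiles with gene probe sets.

Each cluster's anchor (the member site nearest the cluster's positional
centroid) is matched against every expression probe set on the same
chromosome.  An association is emitted when the anchor lies within the
probe-set range itself or within a symmetric window (20,000 bp by default)
around it; the window absorbs the positional uncertainty of locating a
CpG island relative to its gene.  Strand is ignored.  A representative
may match several probe sets and a probe set several representatives.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict

import numpy as np

from .datatypes import Association, ClusterModel, ExpressionProbeSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 20_000


def associate(
    models: list[ClusterModel],
    probesets: list[ExpressionProbeSet],
    window: int = DEFAULT_WINDOW_BP,
) -> list[Association]:
    """All (representative, probe set) pairs with the anchor inside
    [start - window, end + window], both ends inclusive.

    Implemented as a sorted sweep per chromosome; output order is
    deterministic regardless of input order.  Zero associations is legal
    but logged as a warning.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    by_chrom: dict[str, list[ExpressionProbeSet]] = defaultdict(list)
    for p in probesets:
        by_chrom[p.chromosome].append(p)
    # sweep structures: probe sets sorted by extended start, with a running
    # maximum of extended ends for pruning
    index: dict[str, tuple[list[int], list[ExpressionProbeSet], list[int]]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.start, p.probeset_id))
        starts = [p.start - window for p in plist]
        max_end = []
        running = -(10**18)
        for p in plist:
            running = max(running, p.end + window)
            max_end.append(running)
        index[chrom] = (starts, plist, max_end)

    out: list[Association] = []
    for model in sorted(models, key=lambda m: m.region_id):
        starts_plist = index.get(model.chromosome)
        if starts_plist is None:
            continue
        starts, plist, max_end = starts_plist
        for cluster, (anchor_site, anchor_pos) in enumerate(model.anchors):
            hi = bisect_right(starts, anchor_pos)
            # scan left from hi; stop once the running max extended end
            # falls short of the anchor (no earlier interval can reach it)
            for j in range(hi - 1, -1, -1):
                if max_end[j] < anchor_pos:
                    break
                p = plist[j]
                if p.start - window <= anchor_pos <= p.end + window:
                    if p.start <= anchor_pos <= p.end:
                        dist = 0
                    else:
                        dist = min(abs(anchor_pos - p.start), abs(anchor_pos - p.end))
                    out.append(
                        Association(
                            assoc_id=f"{model.region_id}.c{cluster}|{p.probeset_id}",
                            region_id=model.region_id,
                            cluster=cluster,
                            gene=p.gene,
                            probeset_id=p.probeset_id,
                            anchor_site=anchor_site,
                            anchor_chrom=model.chromosome,
                            anchor_pos=anchor_pos,
                            distance_to_probeset=dist,
                            M_profile=np.asarray(model.representatives[cluster], dtype=float),
                            E_profile=np.asarray(p.profile, dtype=float),
                        )
                    )
    out.sort(key=lambda a: a.assoc_id)
    if not out:
        logger.warning("associate: no associations produced")
    else:
        logger.info("associate: %d associations", len(out))
    return out
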