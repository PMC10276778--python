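"""Published reference values for the tissue-engineering horizon-scan corpus.

A published citation-network analysis of the tissue-engineering /
additive-manufacturing literature (233,968 Web of Science records,
1900-2021) reports that 197,948 records (84%) form the largest connected
component, clustered into 78 communities, with the top ten clusters
holding more than 80% of the clustered articles.  The per-cluster sizes
of those top ten clusters are reproduced below; they serve as worked-
example inputs for the ratio arithmetic the toolkit logs on its own runs
(component share, cumulative cluster coverage).
"""

from __future__ import annotations

#: total records retrieved for the reference corpus
TOTAL_RECORDS = 233_968

#: records in the largest connected component ("84%" as printed)
COMPONENT_SIZE = 197_948

#: number of Louvain clusters reported for the component
N_CLUSTERS = 78

#: sizes of the ten largest clusters, in cluster-number order 1..10
TOP10_CLUSTER_SIZES = (
    29_186,  # scaffolds for tissue engineering
    25_067,  # stem cells
    19_199,  # 3D bio-printing
    18_203,  # additive manufacturing
    17_762,  # conductive materials
    15_865,  # microfluidics
    14_243,  # metal additive manufacturing
    11_200,  # vascular/cardiac patches, decellularized tissue
    8_137,   # tissue engineering for muscle
    7_816,   # tissue engineering for cartilage
)


def component_share_pct() -> float:
    """Largest-component share of all retrieved records, in percent."""
    return 100.0 * COMPONENT_SIZE / TOTAL_RECORDS


def top10_share_pct() -> float:
    """Share of clustered articles held by the ten largest clusters, in percent."""
    return 100.0 * sum(TOP10_CLUSTER_SIZES) / COMPONENT_SIZE
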