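"""Benchmark mixture-weight constants.

The reference vector defines cluster abundances for the cluster-number
benchmark (1 x 0.1425, 2 x 0.07125, 4 x 0.035625, 8 x 0.0178125,
16 x 0.00890625, 32 x 0.004453125, 64 x 0.002226562, in decreasing
order).  The responder benchmark uses two fixed 125-component vectors:
non-responders carry the predictive component (index 119, 0-based) at
weight 0.0011; responders carry it doubled to 0.0022 with the other 124
weights proportionally reduced.
"""

import numpy as np

REFERENCE_WEIGHTS = np.array([
    0.1425, 0.07125, 0.07125, 0.035625, 0.035625, 0.035625,
    0.035625, 0.0178125, 0.0178125, 0.0178125, 0.0178125, 0.0178125,
    0.0178125, 0.0178125, 0.0178125, 0.00890625, 0.00890625, 0.00890625,
    0.00890625, 0.00890625, 0.00890625, 0.00890625, 0.00890625, 0.00890625,
    0.00890625, 0.00890625, 0.00890625, 0.00890625, 0.00890625, 0.00890625,
    0.00890625, 0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125,
    0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125,
    0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125,
    0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125,
    0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125, 0.004453125,
    0.004453125, 0.004453125, 0.004453125, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562, 0.002226562,
    0.002226562,
])

NONRESPONDER_WEIGHTS = np.array([
    0.16155, 0.0712, 0.0712, 0.0356, 0.0356, 0.0356,
    0.0356, 0.0178, 0.0178, 0.0178, 0.0178, 0.0178,
    0.0178, 0.0178, 0.0178, 0.0089, 0.0089, 0.0089,
    0.0089, 0.0089, 0.0089, 0.0089, 0.0089, 0.0089,
    0.0089, 0.0089, 0.0089, 0.0089, 0.0089, 0.0089,
    0.0089, 0.0045, 0.0045, 0.0045, 0.0045, 0.0045,
    0.0045, 0.0045, 0.0045, 0.0045, 0.0045, 0.0045,
    0.0045, 0.0045, 0.0045, 0.0045, 0.0045, 0.0045,
    0.0045, 0.0045, 0.0045, 0.0045, 0.0045, 0.0045,
    0.0045, 0.0045, 0.0045, 0.0045, 0.0045, 0.0045,
    0.0045, 0.0045, 0.0045, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.0022, 0.0022, 0.0022, 0.0022,
    0.0022, 0.0022, 0.00209, 0.00198, 0.00187, 0.00176,
    0.00165, 0.00154, 0.00143, 0.00132, 0.00121, 0.0011,
    0.0011, 0.0011, 0.0011, 0.0011, 0.0011,
])

RESPONDER_WEIGHTS = np.array([
    0.16120344, 0.07105221, 0.07105221, 0.03553053, 0.03553053, 0.03553053,
    0.03553053, 0.01776969, 0.01776969, 0.01776969, 0.01776969, 0.01776969,
    0.01776969, 0.01776969, 0.01776969, 0.00888927, 0.00888927, 0.00888927,
    0.00888927, 0.00888927, 0.00888927, 0.00888927, 0.00888927, 0.00888927,
    0.00888927, 0.00888927, 0.00888927, 0.00888927, 0.00888927, 0.00888927,
    0.00888927, 0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895,
    0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895,
    0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895,
    0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895,
    0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895, 0.00449895,
    0.00449895, 0.00449895, 0.00449895, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401, 0.00220401,
    0.00220401, 0.00220401, 0.00209425, 0.0019845, 0.00187474, 0.00176498,
    0.00165522, 0.00154546, 0.00143571, 0.00132595, 0.00121619, 0.0022,
    0.00110643, 0.00110643, 0.00110643, 0.00110643, 0.00110643,
])

PREDICTIVE_INDEX = 119  # 0-based position of the predictive component
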