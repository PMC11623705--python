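"""Published benchmark numbers for the NHANES actigraphy prediction tasks.

These are the reported test AUCs of the original pretrained actigraphy
transformer (PAT) release and its baselines on the NHANES 2013-2014
supervised tasks, shipped as data so the reporting arithmetic (average AUC
across training sizes, percentage-point improvements, cohort bookkeeping)
is recomputable offline.  They are reference inputs, not outputs of this
package's models.
"""

from __future__ import annotations

__all__ = ["NHANES_PRETRAIN_COHORTS", "NHANES_PRETRAIN_TOTAL",
           "NHANES_HELD_OUT_COHORT", "NHANES_ALL_TOTAL",
           "BENZO_TRAIN_SIZES", "BENZO_BENCHMARK", "BENZO_AVG_PRINTED",
           "TASK_AVG_AUC", "is_pat_model"]

# NHANES actigraphy cohorts (participants with one week of minute-level data)
NHANES_PRETRAIN_COHORTS = {
    "2003-2004": 7_176,
    "2005-2006": 7_455,
    "2011-2012": 6_907,
}
NHANES_PRETRAIN_TOTAL = 21_538           # pretraining pool
NHANES_HELD_OUT_COHORT = 7_769           # 2013-2014, held out for supervision
NHANES_ALL_TOTAL = 29_307                # every cohort combined

# Benzodiazepine task: per-training-size test AUCs (test set of 2,000) and
# the printed average-AUC column.
BENZO_TRAIN_SIZES = (500, 1_000, 2_500, 5_769)
BENZO_BENCHMARK = {
    "LSTM":                 (0.501, 0.487, 0.474, 0.512),
    "LSTM (smoothing)":     (0.506, 0.508, 0.482, 0.499),
    "Wavelet Transform":    (0.674, 0.625, 0.598, 0.583),
    "CNN-1D":               (0.621, 0.630, 0.640, 0.637),
    "CNN-1D (smoothing)":   (0.633, 0.634, 0.644, 0.646),
    "Conv LSTM (smoothing)": (0.666, 0.680, 0.653, 0.671),
    "Conv LSTM":            (0.663, 0.681, 0.650, 0.677),
    "CNN-3D":               (0.683, 0.693, 0.693, 0.703),
    "CNN-3D (smoothing)":   (0.677, 0.695, 0.696, 0.719),
    "PAT-S":                (0.706, 0.718, 0.677, 0.703),
    "PAT Conv-S":           (0.737, 0.711, 0.722, 0.735),
    "PAT-M":                (0.743, 0.745, 0.742, 0.745),
    "PAT Conv-M":           (0.753, 0.756, 0.760, 0.773),
    "PAT Conv-L":           (0.763, 0.756, 0.754, 0.773),
    "PAT-L":                (0.771, 0.765, 0.760, 0.771),
}
BENZO_AVG_PRINTED = {
    "LSTM": 0.493, "LSTM (smoothing)": 0.499, "Wavelet Transform": 0.620,
    "CNN-1D": 0.632, "CNN-1D (smoothing)": 0.639,
    "Conv LSTM (smoothing)": 0.667, "Conv LSTM": 0.668,
    "CNN-3D": 0.693, "CNN-3D (smoothing)": 0.697,
    "PAT-S": 0.701, "PAT Conv-S": 0.726, "PAT-M": 0.744,
    "PAT Conv-M": 0.761, "PAT Conv-L": 0.762, "PAT-L": 0.767,
}

# Other tasks: published average AUC (across the four training sizes) only.
TASK_AVG_AUC = {
    "SSRI usage": {
        "LSTM": 0.527, "LSTM (smoothing)": 0.523, "Wavelet Transform": 0.674,
        "CNN-1D": 0.616, "CNN-1D (smoothing)": 0.611,
        "Conv LSTM (smoothing)": 0.655, "Conv LSTM": 0.606,
        "CNN-3D": 0.677, "CNN-3D (smoothing)": 0.680,
        "PAT-S": 0.641, "PAT Conv-S": 0.656, "PAT-M": 0.690,
        "PAT Conv-M": 0.668, "PAT Conv-L": 0.695, "PAT-L": 0.700,
    },
    "Sleep Disorder": {
        "LSTM": 0.494, "LSTM (smoothing)": 0.506, "Wavelet Transform": 0.529,
        "CNN-1D": 0.563, "CNN-1D (smoothing)": 0.558,
        "Conv LSTM (smoothing)": 0.609, "Conv LSTM": 0.606,
        "CNN-3D": 0.608, "CNN-3D (smoothing)": 0.605,
        "PAT-S": 0.587, "PAT Conv-S": 0.616, "PAT-M": 0.641,
        "PAT Conv-M": 0.616, "PAT Conv-L": 0.631, "PAT-L": 0.632,
    },
    "Sleep Abnormalities": {
        "LSTM": 0.513, "LSTM (smoothing)": 0.515, "Wavelet Transform": 0.525,
        "CNN-1D": 0.534, "CNN-1D (smoothing)": 0.519,
        "Conv LSTM (smoothing)": 0.579, "Conv LSTM": 0.585,
        "CNN-3D": 0.606, "CNN-3D (smoothing)": 0.615,
        "PAT-S": 0.555, "PAT Conv-S": 0.573, "PAT-M": 0.641,
        "PAT Conv-M": 0.627, "PAT Conv-L": 0.659, "PAT-L": 0.665,
    },
    "Depression": {
        "LSTM": 0.489, "LSTM (smoothing)": 0.506, "Wavelet Transform": 0.523,
        "CNN-1D": 0.522, "CNN-1D (smoothing)": 0.517,
        "Conv LSTM (smoothing)": 0.547, "Conv LSTM": 0.550,
        "CNN-3D": 0.583, "CNN-3D (smoothing)": 0.586,
        "PAT-S": 0.560, "PAT Conv-S": 0.587, "PAT-M": 0.559,
        "PAT Conv-M": 0.594, "PAT Conv-L": 0.610, "PAT-L": 0.589,
    },
}


def is_pat_model(name: str) -> bool:
    return name.startswith("PAT")
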