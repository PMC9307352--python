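"""Published results of the ovarian-cancer microarray study this pipeline
re-implements, kept as consistency fixtures for the table audit.

Each row pairs the study's reported 100-sample confusion matrix and mean
MSE for one (feature method x classifier x feature-selection) cell with the
eight printed performance metrics.  :func:`ovaclass.evaluation.audit_metric_table`
recomputes the metrics from the confusion counts and verifies the printed
values; the rows are *not* used to train or tune anything.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import ConfusionMatrix

__all__ = ["ReferenceRow", "reference_rows"]


@dataclass(frozen=True)
class ReferenceRow:
    method: str
    classifier: str
    selection: bool
    tp: int
    tn: int
    fp: int
    fn: int
    mse: float
    accuracy: float
    precision: float
    f1: float
    mcc: float
    fm: float
    error_rate: float
    jaccard: float
    csi: float

    @property
    def confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix(self.tp, self.tn, self.fp, self.fn)

    @property
    def printed_metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "fm": self.fm,
            "error_rate": self.error_rate,
            "jaccard": self.jaccard,
            "csi": self.csi,
        }


# (method, classifier, tp, tn, fp, fn, mse,
#  accuracy, precision, f1, mcc, fm, error, jaccard, csi)
_WITHOUT_SELECTION = [
    ("FCM", "GMM", 44, 26, 24, 6, 1.82e-04, 70, 64.706, 74.576, 0.429, 0.755, 30, 59.459, 52.706),
    ("FCM", "DFA", 48, 26, 24, 2, 2.00e-04, 74, 66.667, 78.689, 0.535, 0.800, 26, 64.865, 62.667),
    ("FCM", "NLR", 47, 26, 24, 3, 2.10e-04, 73, 66.197, 77.686, 0.507, 0.789, 27, 63.514, 60.197),
    ("FCM", "BLDC", 39, 27, 23, 11, 1.06e-04, 66, 62.903, 69.643, 0.330, 0.700, 34, 53.425, 40.903),
    ("FCM", "LR", 40, 27, 23, 10, 3.03e-05, 67, 63.492, 70.796, 0.352, 0.713, 33, 54.795, 43.492),
    ("FCM", "KNN", 34, 26, 24, 16, 1.82e-04, 60, 58.621, 62.963, 0.203, 0.631, 40, 45.946, 26.621),
    ("SDA", "GMM", 42, 43, 7, 8, 4.62e-06, 85, 85.714, 84.848, 0.700, 0.849, 15, 73.684, 69.714),
    ("SDA", "DFA", 46, 40, 10, 4, 6.98e-06, 86, 82.143, 86.792, 0.725, 0.869, 14, 76.667, 74.143),
    ("SDA", "NLR", 48, 44, 6, 2, 2.38e-06, 92, 88.889, 92.308, 0.843, 0.924, 8, 85.714, 84.889),
    ("SDA", "BLDC", 35, 26, 24, 15, 2.06e-04, 61, 59.322, 64.220, 0.224, 0.644, 39, 47.297, 29.322),
    ("SDA", "LR", 36, 26, 24, 14, 2.34e-04, 62, 60.000, 65.455, 0.245, 0.657, 38, 48.649, 32.000),
    ("SDA", "KNN", 28, 27, 23, 22, 1.75e-04, 55, 54.902, 55.446, 0.100, 0.554, 45, 38.356, 10.902),
    ("HILBERT", "GMM", 30, 27, 23, 20, 1.85e-04, 57, 56.604, 58.252, 0.140, 0.583, 43, 41.096, 16.604),
    ("HILBERT", "DFA", 47, 26, 24, 3, 2.01e-04, 73, 66.197, 77.686, 0.507, 0.789, 27, 63.514, 60.197),
    ("HILBERT", "NLR", 48, 26, 24, 2, 2.10e-04, 74, 66.667, 78.689, 0.535, 0.800, 26, 64.865, 62.667),
    ("HILBERT", "BLDC", 37, 40, 10, 13, 1.80e-05, 77, 78.723, 76.289, 0.541, 0.763, 23, 61.667, 52.723),
    ("HILBERT", "LR", 33, 42, 8, 17, 2.67e-05, 75, 80.488, 72.527, 0.508, 0.729, 25, 56.897, 46.488),
    ("HILBERT", "KNN", 28, 27, 23, 22, 1.68e-04, 55, 54.902, 55.446, 0.100, 0.554, 45, 38.356, 10.902),
    ("FFT", "GMM", 33, 42, 8, 17, 2.77e-05, 75, 80.488, 72.527, 0.508, 0.729, 25, 56.897, 46.488),
    ("FFT", "DFA", 45, 28, 22, 5, 7.31e-05, 73, 67.164, 76.923, 0.489, 0.777, 27, 62.500, 57.164),
    ("FFT", "NLR", 45, 29, 21, 5, 4.33e-05, 74, 68.182, 77.586, 0.507, 0.783, 26, 63.380, 58.182),
    ("FFT", "BLDC", 34, 34, 16, 16, 3.97e-05, 68, 68.000, 68.000, 0.360, 0.680, 32, 51.515, 36.000),
    ("FFT", "LR", 29, 29, 21, 21, 7.87e-05, 58, 58.000, 58.000, 0.160, 0.580, 42, 40.845, 16.000),
    ("FFT", "KNN", 26, 41, 9, 24, 1.34e-04, 67, 74.286, 61.176, 0.356, 0.622, 33, 44.068, 26.286),
    ("DCT", "GMM", 36, 41, 9, 14, 1.73e-05, 77, 80.000, 75.789, 0.543, 0.759, 23, 61.017, 52.000),
    ("DCT", "DFA", 45, 37, 13, 5, 1.19e-05, 82, 77.586, 83.333, 0.648, 0.836, 18, 71.429, 67.586),
    ("DCT", "NLR", 46, 29, 21, 4, 3.59e-05, 75, 68.657, 78.632, 0.532, 0.795, 25, 64.789, 60.657),
    ("DCT", "BLDC", 37, 36, 14, 13, 2.68e-05, 73, 72.549, 73.267, 0.460, 0.733, 27, 57.813, 46.549),
    ("DCT", "LR", 31, 29, 21, 19, 6.92e-05, 60, 59.615, 60.784, 0.200, 0.608, 40, 43.662, 21.615),
    ("DCT", "KNN", 29, 26, 24, 21, 2.21e-04, 55, 54.717, 56.311, 0.100, 0.563, 45, 39.189, 12.717),
]

_WITH_SELECTION = [
    ("FCM", "GMM", 30, 36, 14, 20, 4.58e-05, 66, 68.182, 63.830, 0.322, 0.640, 34, 46.875, 28.182),
    ("FCM", "DFA", 28, 41, 9, 22, 5.41e-05, 69, 75.676, 64.368, 0.394, 0.651, 31, 47.458, 31.676),
    ("FCM", "NLR", 30, 33, 17, 20, 5.54e-05, 63, 63.830, 61.856, 0.260, 0.619, 37, 44.776, 23.830),
    ("FCM", "BLDC", 36, 29, 21, 14, 4.82e-05, 65, 63.158, 67.290, 0.303, 0.674, 35, 50.704, 35.158),
    ("FCM", "LR", 44, 33, 17, 6, 2.36e-05, 77, 72.131, 79.279, 0.554, 0.797, 23, 65.672, 60.131),
    ("FCM", "KNN", 29, 27, 23, 21, 1.25e-04, 56, 55.769, 56.863, 0.120, 0.569, 44, 39.726, 13.769),
    ("SDA", "GMM", 42, 34, 16, 8, 2.45e-05, 76, 72.414, 77.778, 0.527, 0.780, 24, 63.636, 56.414),
    ("SDA", "DFA", 41, 27, 23, 9, 9.06e-05, 68, 64.063, 71.930, 0.375, 0.725, 32, 56.164, 46.063),
    ("SDA", "NLR", 26, 27, 23, 24, 2.62e-04, 53, 53.061, 52.525, 0.060, 0.525, 47, 35.616, 5.061),
    ("SDA", "BLDC", 43, 29, 21, 7, 4.18e-05, 72, 67.188, 75.439, 0.458, 0.760, 28, 60.563, 53.188),
    ("SDA", "LR", 34, 29, 21, 16, 5.55e-05, 63, 61.818, 64.762, 0.261, 0.648, 37, 47.887, 29.818),
    ("SDA", "KNN", 28, 27, 23, 22, 1.42e-04, 55, 54.902, 55.446, 0.100, 0.554, 45, 38.356, 10.902),
    ("HILBERT", "GMM", 29, 34, 16, 21, 5.53e-05, 63, 64.444, 61.053, 0.261, 0.611, 37, 43.939, 22.444),
    ("HILBERT", "DFA", 49, 27, 23, 1, 1.05e-04, 76, 68.056, 80.328, 0.579, 0.817, 24, 67.123, 66.056),
    ("HILBERT", "NLR", 44, 35, 15, 6, 1.71e-05, 79, 74.576, 80.734, 0.590, 0.810, 21, 67.692, 62.576),
    ("HILBERT", "BLDC", 45, 37, 13, 5, 1.30e-05, 82, 77.586, 83.333, 0.648, 0.836, 18, 71.429, 67.586),
    ("HILBERT", "LR", 44, 26, 24, 6, 1.92e-04, 70, 64.706, 74.576, 0.429, 0.755, 30, 59.459, 52.706),
    ("HILBERT", "KNN", 33, 37, 13, 17, 3.43e-05, 70, 71.739, 68.750, 0.401, 0.688, 30, 52.381, 37.739),
    ("FFT", "GMM", 29, 42, 8, 21, 4.53e-05, 71, 78.378, 66.667, 0.435, 0.674, 29, 50.000, 36.378),
    ("FFT", "DFA", 45, 41, 9, 5, 6.42e-06, 86, 83.333, 86.538, 0.722, 0.866, 14, 76.271, 73.333),
    ("FFT", "NLR", 35, 27, 23, 15, 9.02e-05, 62, 60.345, 64.815, 0.243, 0.650, 38, 47.945, 30.345),
    ("FFT", "BLDC", 29, 27, 23, 21, 1.63e-04, 56, 55.769, 56.863, 0.120, 0.569, 44, 39.726, 13.769),
    ("FFT", "LR", 35, 26, 24, 15, 1.87e-04, 61, 59.322, 64.220, 0.224, 0.644, 39, 47.297, 29.322),
    ("FFT", "KNN", 27, 31, 19, 23, 1.15e-04, 58, 58.696, 56.250, 0.161, 0.563, 42, 39.130, 12.696),
    ("DCT", "GMM", 46, 42, 8, 4, 4.64e-06, 88, 85.185, 88.462, 0.762, 0.885, 12, 79.310, 77.185),
    ("DCT", "DFA", 46, 27, 23, 4, 8.89e-05, 73, 66.667, 77.311, 0.497, 0.783, 27, 63.014, 58.667),
    ("DCT", "NLR", 45, 28, 22, 5, 7.92e-05, 73, 67.164, 76.923, 0.489, 0.777, 27, 62.500, 57.164),
    ("DCT", "BLDC", 37, 36, 14, 13, 2.28e-05, 73, 72.549, 73.267, 0.460, 0.733, 27, 57.813, 46.549),
    ("DCT", "LR", 34, 42, 8, 16, 2.42e-05, 76, 80.952, 73.913, 0.527, 0.742, 24, 58.621, 48.952),
    ("DCT", "KNN", 28, 33, 17, 22, 6.80e-05, 61, 62.222, 58.947, 0.221, 0.590, 39, 41.791, 18.222),
]


def _build(rows: list[tuple], selection: bool) -> list[ReferenceRow]:
    return [
        ReferenceRow(
            method=r[0], classifier=r[1], selection=selection,
            tp=r[2], tn=r[3], fp=r[4], fn=r[5], mse=r[6],
            accuracy=r[7], precision=r[8], f1=r[9], mcc=r[10], fm=r[11],
            error_rate=r[12], jaccard=r[13], csi=r[14],
        )
        for r in rows
    ]


def reference_rows(selection: bool | None = None) -> list[ReferenceRow]:
    """All 60 published rows, optionally filtered by feature-selection arm."""
    rows = _build(_WITHOUT_SELECTION, False) + _build(_WITH_SELECTION, True)
    if selection is None:
        return rows
    return [r for r in rows if r.selection is selection]
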