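import numpy as np
import pytest

from chemvs.chem_io import parse_smiles
from chemvs.descriptors import compute_descriptor_vector
from chemvs.synth import fixture_molecules, fixture_golden_values


@pytest.fixture(scope="session")
def fixture_graphs():
    """All packaged fixture molecules, parsed once, keyed by name."""
    return {name: parse_smiles(s, name) for s, name in fixture_molecules()}


@pytest.fixture(scope="session")
def fixture_vectors(fixture_graphs):
    """Descriptor vectors for all fixture molecules, computed once."""
    return {name: compute_descriptor_vector(g) for name, g in fixture_graphs.items()}


@pytest.fixture(scope="session")
def golden_values():
    return fixture_golden_values()


# printed per-fold confusion counts and statistics of the three
# cross-validation studies (SVM / kNN / PNN), used as golden data:
# rows are (TP, FN, TN, FP, SE%, SP%, Q%, C)
CV_TABLES = {
    "svm": [
        (320, 21, 12651, 13, 93.84, 99.90, 99.74, 0.948),
        (324, 17, 12650, 14, 95.01, 99.89, 99.76, 0.953),
        (324, 17, 12640, 24, 95.01, 99.81, 99.68, 0.939),
        (318, 22, 12642, 21, 93.53, 99.83, 99.67, 0.935),
        (322, 18, 12643, 20, 94.71, 99.84, 99.71, 0.943),
    ],
    "knn": [
        (302, 39, 12635, 29, 88.56, 99.77, 99.48, 0.896),
        (313, 28, 12620, 44, 91.79, 99.65, 99.45, 0.894),
        (311, 30, 12610, 54, 91.20, 99.57, 99.35, 0.878),
        (316, 24, 12619, 44, 92.94, 99.65, 99.48, 0.901),
        (302, 38, 12632, 31, 88.82, 99.76, 99.47, 0.895),
    ],
    "pnn": [
        (319, 22, 12413, 251, 93.55, 98.02, 97.90, 0.715),
        (324, 17, 12380, 284, 95.01, 97.76, 97.69, 0.702),
        (330, 11, 12395, 269, 96.77, 97.88, 97.85, 0.722),
        (330, 10, 12389, 274, 97.06, 97.84, 97.82, 0.720),
        (318, 22, 12413, 250, 93.53, 98.03, 97.91, 0.715),
    ],
}

# printed Average / SD / SE(mean) summary rows per study:
# {stat: (average, sd, sem)} with averages on the printed scale
CV_SUMMARIES = {
    "svm": {"se": (94.42, 0.0069, 0.0031), "sp": (99.85, 0.0004, 0.0002),
            "q": (99.71, 0.0004, 0.0002), "c": (0.944, 0.0072, 0.0032)},
    "knn": {"se": (90.66, 0.0191, 0.0085), "sp": (99.68, 0.0008, 0.0004),
            "q": (99.44, 0.0005, 0.0002), "c": (0.893, 0.0085, 0.0038)},
    "pnn": {"se": (95.19, 0.0169, 0.0076), "sp": (97.90, 0.0012, 0.0005),
            "q": (97.83, 0.0009, 0.0004), "c": (0.715, 0.0075, 0.0034)},
}
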