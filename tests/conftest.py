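import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def law_of_cosines_angle(point, target):
    """Independent oracle: angle at B from the three side lengths."""
    A = np.zeros(2)
    B = np.asarray(point, float)
    C = np.asarray(target, float)
    ab = np.linalg.norm(A - B)
    bc = np.linalg.norm(C - B)
    ac = np.linalg.norm(C - A)
    cosb = (ab**2 + bc**2 - ac**2) / (2 * ab * bc)
    return float(np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0))))


@pytest.fixture
def tiny_frame():
    """Three rail rows and two choice rows for one species."""
    return pd.DataFrame(
        {
            "species": ["fly"] * 5,
            "treatment": ["rail", "rail", "rail", "choice", "choice"],
            "rail": ["1:1", "1:2", "2:1", None, None],
            "protein": [25.0, 18.0, 24.0, 9.0, 11.0],
            "carbohydrate": [25.0, 36.0, 12.0, 39.0, 41.0],
        }
    )


@pytest.fixture
def drosophila_style_frame():
    """Seven-rail design mirroring classic fly choice experiments."""
    rails = ["0:1", "1:16", "1:8", "1:4", "1:2", "1:1", "2:1"]
    rng = np.random.default_rng(7)
    rows = []
    for rail in rails:
        a, b = (float(x) for x in rail.split(":"))
        d = np.array([a, b]) / np.hypot(a, b)
        for _ in range(6):
            p = d * 40 + rng.normal(0, 1.5, 2)
            rows.append(["fly", "rail", rail, max(p[0], 0.0), max(p[1], 0.0)])
    for _ in range(5):
        rows.append(["fly", "choice", None, 10 + rng.normal(0, 1), 40 + rng.normal(0, 1)])
    return pd.DataFrame(
        rows, columns=["species", "treatment", "rail", "protein", "carbohydrate"]
    )
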