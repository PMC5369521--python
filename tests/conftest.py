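import numpy as np
import pytest

from tsfitge import pipeline
from tsfitge.synthetic import (
    generate_proteome,
    ground_truth_positions,
    make_design,
    render_gel,
)


@pytest.fixture(scope="session")
def mtx_run():
    """Methotrexate-analog image run: 200 proteins, one +8 °C target.

    Session-scoped because rendering and analyzing eight gels is the
    single most expensive fixture in the suite.
    """
    design = make_design(seed=11)
    proteome = generate_proteome(
        200, 1, 0, seed=11,
        param_ranges={"delta_tm": (8.0, 8.0)},
        min_separation_px=8.0, image_shape=design.image_shape,
    )
    gels = {
        design.temperatures[i]: render_gel(proteome, design, i)
        for i in range(len(design.temperatures))
    }
    result = pipeline.analyze_gels(gels, pipeline.RunConfig())
    return {"design": design, "proteome": proteome, "gels": gels, "result": result}


def track_for_species(result, proteome, design, species_id):
    """The track whose baseline spot is nearest a species' true position."""
    truth = {
        r["species_id"]: (r["x"], r["y"])
        for r in ground_truth_positions(proteome, design, 0)
    }
    tx, ty = truth[species_id]
    return min(
        result["tracks"],
        key=lambda tr: (tr.reference_spot.x - tx) ** 2 + (tr.reference_spot.y - ty) ** 2,
    )


def detection_metrics(spots, truth_rows, radius=2.0):
    """Recall / precision / centroid RMS against ground-truth positions."""
    from scipy.spatial import cKDTree

    txy = np.array([[r["x"], r["y"]] for r in truth_rows])
    sxy = np.array([[s.x, s.y] for s in spots])
    if len(sxy) == 0:
        return 0.0, 0.0, np.inf
    d, j = cKDTree(sxy).query(txy, k=1)
    matched = d <= radius
    used, tp = set(), 0
    for di, ji in zip(d, j):
        if di <= radius and ji not in used:
            used.add(ji)
            tp += 1
    recall = float(matched.mean())
    precision = tp / len(sxy)
    rms = float(np.sqrt(np.mean(d[matched] ** 2))) if matched.any() else np.inf
    return recall, precision, rms
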