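"""Regenerate the JSON files under src/dentage/data/ (development helper)."""
import json
from pathlib import Path

import numpy as np
from numpy.polynomial import Polynomial

DATA = Path(__file__).resolve().parents[1] / "src" / "dentage" / "data"
DATA.mkdir(exist_ok=True)

BOYS = [
    (25.8, 4.28746), (27.5, 4.63997), (28.6, 4.84737), (30.2, 5.12152),
    (31.4, 5.30676), (32.9, 5.51512), (43.4, 6.38282), (45.1, 6.4484),
    (49, 6.54762), (50.3, 6.56851), (52, 6.58939), (52.1, 6.59044),
    (52.2, 6.59147), (52.8, 6.5973), (53.9, 6.60675), (56.8, 6.62817),
    (58.9, 6.64555), (60.8, 6.66675), (65, 6.74862), (67, 6.81243),
    (67.5, 6.83155), (67.6, 6.83554), (67.7, 6.83958), (71.7, 7.05245),
    (73, 7.14604), (74, 7.22733), (75.6, 7.37547), (77.6, 7.59454),
    (77.7, 7.60654), (77.9, 7.63085), (79.4, 7.8268), (81.3, 8.11119),
    (81.5, 8.1436), (82.1, 8.24375), (83.5, 8.49501), (83.6, 8.51392),
    (84.5, 8.69009), (84.9, 8.77189), (85.6, 8.92035), (85.8, 8.96403),
    (85.9, 8.98608), (86, 9.00827), (87.3, 9.30993), (87.9, 9.45756),
    (89.6, 9.90584), (90.3, 10.10369), (90.4, 10.1326), (90.5, 10.16168),
    (91.4, 10.43079), (91.6, 10.49243), (92.4, 10.74578), (93.1, 10.97653),
    (93.4, 11.07805), (93.5, 11.11225), (93.8, 11.21591), (94.1, 11.32118),
    (94.5, 11.46407), (94.7, 11.53661), (95.3, 11.75866), (96.1, 12.06518),
    (96.2, 12.10434), (97, 12.42458), (98.8, 13.19098),
]
GIRLS = [
    (27.2, 4.08377), (27.4, 4.12524), (30.2, 4.64983), (30.3, 4.66671),
    (33.6, 5.15701), (35.1, 5.3399), (35.9, 5.42803), (39.4, 5.74337),
    (45.2, 6.05669), (47.9, 6.13495), (50.8, 6.18559), (52, 6.19902),
    (59.4, 6.24147), (60.5, 6.2489), (61.2, 6.25469), (63.6, 6.28319),
    (63.6, 6.28319), (63.7, 6.28473), (64.5, 6.29826), (65, 6.30787),
    (65.5, 6.31843), (67.8, 6.38106), (67.9, 6.38436), (71.3, 6.53046),
    (72, 6.56966), (77.2, 6.98061), (79.3, 7.21594), (79.6, 7.25324),
    (79.9, 7.29151), (81.4, 7.49764), (82.1, 7.60258), (82.7, 7.69714),
    (82.9, 7.72963), (85, 8.10086), (86.3, 8.35951), (87.1, 8.53019),
    (87.2, 8.55216), (87.4, 8.59652), (88.1, 8.75631), (88.3, 8.80327),
    (88.4, 8.82697), (89.1, 8.99705), (89.3, 9.04699), (89.5, 9.09754),
    (90.5, 9.35954), (91.5, 9.63728), (91.7, 9.69475), (92.2, 9.84131),
    (92.9, 10.05345), (93.7, 10.30601), (94, 10.40356), (94.2, 10.46946),
    (94.4, 10.53605), (95, 10.74007), (95.3, 10.84448), (95.7, 10.98622),
    (96, 11.09443), (96.1, 11.13086), (96.3, 11.20428), (96.8, 11.39107),
    (97.1, 11.50539), (98.6, 12.10261), (98.9, 12.22728), (100, 12.69963),
]

PUBLISHED = {
    "male": {"b0": -7.424, "b1": 0.741, "b2": -0.013, "b3": 0.00007863},
    "female": {"b0": -8.269, "b1": 0.757, "b2": -0.013, "b3": 0.00007782},
}

PROV_TABLE = "published Saudi prediction table (calibration study, 2013)"
PROV_CUBIC = (
    "least-squares cubic refit from the published Saudi prediction table; "
    "published rounded coefficients retained as metadata"
)


def dump(name, doc):
    with open(DATA / name, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


for sex, pairs in (("male", BOYS), ("female", GIRLS)):
    # Tables 9/10 allow a duplicated score row; keep unique scores for the
    # lookup standard (scores must strictly increase).
    uniq = []
    for s, a in pairs:
        if not uniq or s > uniq[-1][0]:
            uniq.append((float(s), float(a)))
    dump(
        f"saudi_{sex}_table.json",
        {
            "name": f"saudi_{sex}",
            "sex": sex,
            "variant": "table",
            "pairs": [[s, a] for s, a in uniq],
            "provenance": PROV_TABLE,
        },
    )
    # Fit on the deduplicated pairs so the shipped coefficients agree
    # exactly with refits from the packaged table (the one duplicated row
    # shifts b0 by ~2e-7, far below every tolerance in play).
    x = np.array([p[0] for p in uniq])
    y = np.array([p[1] for p in uniq])
    coefs = Polynomial.fit(x, y, 3).convert().coef
    dump(
        f"saudi_{sex}_cubic.json",
        {
            "name": f"saudi_{sex}_cubic",
            "sex": sex,
            "variant": "poly",
            "coefficients": {f"b{i}": float(coefs[i]) for i in range(4)},
            "coverage": {"score": [float(x.min()), float(x.max())]},
            "provenance": PROV_CUBIC,
            "published_coefficients": PUBLISHED[sex],
        },
    )

# --- demo weight tables (synthetic, invariant-satisfying; NOT reference) ---
STAGES = ("0", "A", "B", "C", "D", "E", "F", "G", "H")
TEETH = ("I1", "I2", "C", "PM1", "PM2", "M1", "M2")
MAXES = {
    "male": {"I1": 12.0, "I2": 13.0, "C": 14.0, "PM1": 15.0, "PM2": 16.0, "M1": 15.0, "M2": 15.0},
    "female": {"I1": 12.5, "I2": 12.5, "C": 13.5, "PM1": 15.5, "PM2": 15.5, "M1": 15.5, "M2": 15.0},
}
FRACS = {
    "male": (0.0, 0.05, 0.13, 0.23, 0.35, 0.50, 0.66, 0.83, 1.0),
    "female": (0.0, 0.06, 0.15, 0.26, 0.39, 0.54, 0.70, 0.85, 1.0),
}
for sex in ("male", "female"):
    weights = {}
    for tooth in TEETH:
        mx = MAXES[sex][tooth]
        row = {}
        for stage, frac in zip(STAGES, FRACS[sex]):
            row[stage] = round(mx * frac, 3)
        row["H"] = mx  # exact so the full-maturity total is exactly 100
        weights[tooth] = row
    assert abs(sum(weights[t]["H"] for t in TEETH) - 100.0) < 1e-12
    dump(
        f"demo_weights_{sex}.json",
        {
            "sex": sex,
            "provenance": "synthetic demo weight table (placeholder, not literature values)",
            "weights": weights,
        },
    )

# --- demo external standards (placeholder values, schema-valid) ---------
DEMOS = {
    "french_canadian": {"bias": 0.0, "age": None},
    "belgian": {"bias": 1.4, "age": None},
    "kuwaiti": {"bias": -0.45, "age": None},
    "alemran": {"bias": -0.35, "age": [7.5, 17.0]},
}
for key, cfg in DEMOS.items():
    for sex in ("male", "female"):
        grid = [float(s) for s in range(0, 101, 5)]
        base = 0.065 if sex == "male" else 0.068
        ages = [round(3.0 + base * s + 0.00045 * s * s + cfg["bias"], 5) for s in grid]
        doc = {
            "name": f"demo_{key}_{sex}",
            "sex": sex,
            "variant": "table",
            "pairs": [[s, a] for s, a in zip(grid, ages)],
            "provenance": "synthetic demo values; placeholder, not the published standard",
        }
        if cfg["age"]:
            doc["coverage"] = {"age": cfg["age"]}
        dump(f"demo_{key}_{sex}.json", doc)

print("wrote", sorted(p.name for p in DATA.glob("*.json")))
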