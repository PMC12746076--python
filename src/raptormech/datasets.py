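"""Bundled reference data for the six focal raptor species.

Three accipitrids (sharp-shinned hawk, Cooper's hawk, red-tailed hawk) and
three strigids (eastern screech-owl, long-eared owl, great horned owl) make
up the focal comparison. The tables here carry the published species-level
morphometric averages, the lever-arm lengths of the ankle dorsiflexion
model, the prey scenarios used for force/torque comparisons, and the
tendon-test geometry (resting length, cross-sectional area, peak loads)
that parameterises the synthetic tensometer generator.

Note one internal wrinkle in the source tables: the screech-owl outlever is
listed as 0.0312 m in the lever table while its tarsometatarsus length is
32.12 mm; the lever table's value is kept here verbatim so the published
force/torque rows reproduce.
"""

from __future__ import annotations

ACCIPITRID = "accipitrid"
STRIGID = "strigid"

#: species -> (group, tmt length mm, tmt width mm, tubercle distance mm,
#: tubercle-to-trochlea mm), each as (mean, sd). Species-level averages of
#: 10 skeletal specimens each.
FOCAL_MORPHOMETRICS: dict[str, dict] = {
    "Accipiter striatus": {
        "group": ACCIPITRID,
        "tmt_length": (51.4, 3.1),
        "tmt_width": (2.6, 0.46),
        "tubercle_distance": (7.2, 0.55),
        "tubercle_to_trochlea": (44.2, 2.77),
    },
    "Astur cooperii": {
        "group": ACCIPITRID,
        "tmt_length": (66.91, 3.47),
        "tmt_width": (4.8, 0.65),
        "tubercle_distance": (12.66, 1.32),
        "tubercle_to_trochlea": (54.3, 2.53),
    },
    "Buteo jamaicensis": {
        "group": ACCIPITRID,
        "tmt_length": (82.3, 3.2),
        "tmt_width": (7.4, 0.75),
        "tubercle_distance": (18.1, 1.3),
        "tubercle_to_trochlea": (64.2, 2.74),
    },
    "Megascops asio": {
        "group": STRIGID,
        "tmt_length": (32.12, 2.22),
        "tmt_width": (3.49, 0.35),
        "tubercle_distance": (8.92, 0.97),
        "tubercle_to_trochlea": (68.8, 1.37),
    },
    "Asio otus": {
        "group": STRIGID,
        "tmt_length": (41.1, 1.9),
        "tmt_width": (4.5, 0.36),
        "tubercle_distance": (11.9, 1.15),
        "tubercle_to_trochlea": (29.1, 1.06),
    },
    "Bubo virginianus": {
        "group": STRIGID,
        "tmt_length": (62.6, 2.22),
        "tmt_width": (9.6, 0.57),
        "tubercle_distance": (21.3, 0.87),
        "tubercle_to_trochlea": (41.3, 2.1),
    },
}

#: species -> (RA outlever m, FA inlever m) of the published lever model.
FOCAL_LEVER_ARMS: dict[str, tuple[float, float]] = {
    "Accipiter striatus": (0.0514, 0.0072),
    "Astur cooperii": (0.0669, 0.0127),
    "Buteo jamaicensis": (0.0823, 0.0181),
    "Megascops asio": (0.0312, 0.0089),
    "Asio otus": (0.0411, 0.0119),
    "Bubo virginianus": (0.0626, 0.0213),
}

FOCAL_GROUPS: dict[str, str] = {
    sp: rec["group"] for sp, rec in FOCAL_MORPHOMETRICS.items()
}

#: The two prey scenarios applied to every species: an eastern chipmunk and
#: a Virginia opossum (masses in kg).
PREY_SCENARIOS: dict[str, float] = {
    "Tamias striatus": 0.140,
    "Didelphis virginiana": 3.6,
}

#: Tendon-test geometry and outcomes at the 10 % elongation increment:
#: resting length L0 (mm), cross-sectional area A0 (mm^2), species-average
#: peak load (N) and resilience-style left/right leg loads (N).
FOCAL_TENDON_TESTS: dict[str, dict] = {
    "Accipiter striatus": {"L0": 13.12, "A0": 3.85, "peak_load": 10.5,
                           "leg_loads": (8.6, 12.4)},
    "Astur cooperii": {"L0": 14.88, "A0": 5.05, "peak_load": 21.7,
                       "leg_loads": (21.9, 21.5)},
    "Buteo jamaicensis": {"L0": 19.0, "A0": 17.56, "peak_load": 28.0,
                          "leg_loads": (30.1, 25.8)},
    "Megascops asio": {"L0": 13.25, "A0": 2.3, "peak_load": 25.6,
                       "leg_loads": (24.7, 26.4)},
    "Asio otus": {"L0": 17.79, "A0": 6.58, "peak_load": 24.8,
                  "leg_loads": (28.4, 21.2)},
    "Bubo virginianus": {"L0": 20.25, "A0": 19.35, "peak_load": 27.6,
                         "leg_loads": (24.1, 31.0)},
}

#: A small ultrametric demonstration tree (branch lengths in Myr-like
#: units): hawks and owls as reciprocally monophyletic clades, with the six
#: focal species plus six additional tips. Used by the demo pipeline; the
#: statistical machinery is validated on simulated trees.
DEMO_TREE_NEWICK = (
    "((((Accipiter_striatus:20,Astur_cooperii:20):15,"
    "(Buteo_jamaicensis:25,Buteo_swainsoni:25):10):25,"
    "(Haliaeetus_leucocephalus:50,Aquila_chrysaetos:50):10):20,"
    "(((Megascops_asio:30,Bubo_virginianus:30):15,"
    "(Asio_otus:25,Strix_varia:25):20):25,"
    "(Tyto_alba:60,Athene_cunicularia:60):10):10);"
)
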