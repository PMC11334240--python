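"""Shared study configuration for the analysis drivers.

Defines the simulated scanner, the expanded reference basis and the six
study samples (four tissue-mimicking mixtures, two fresh-tissue stand-ins)
with noise levels of the magnitude seen on reconstructed scans of such
phantoms.  Every driver imports from here so the whole analysis shares one
set of study conditions and one master seed.
"""

from __future__ import annotations

from pathlib import Path

import dectissue as dt

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

MASTER_SEED = 20240812

#: True scanner response used by the forward simulation (80 / 140 kV).
TRUE_PARAMS_LOW = dt.StoichiometricParams(8e-5, 3e-3, "80kV")
TRUE_PARAMS_HIGH = dt.StoichiometricParams(3e-5, 1.5e-3, "140kV")

#: Per-sample (sigma_80, sigma_140, n_bubbles) image-noise settings:
#: homogeneous soft samples a few HU, layered/clumped samples tens of HU,
#: the brain sample with trapped-air microbubbles on top.
SAMPLE_NOISE = {
    "muscle": (5.0, 3.0, 0),
    "adipose": (23.0, 25.0, 0),
    "spongiosa_sample": (41.0, 28.0, 0),
    "cortical_sample": (20.0, 15.0, 0),
    "brain": (10.0, 10.0, 40),
    "liver": (9.0, 10.0, 0),
}


def build_expanded_basis() -> dt.TissueBasis:
    """Base published tissues + 135 generated additions (spongiosa,
    lung-air mixtures, dense-bone series)."""
    base = dt.load_reference_basis()
    spong = dt.spongiosa_series(base, 50)
    return dt.expand_basis(
        base, spongiosa=spong, n_low_density=40,
        bone_series=dt.BoneSeriesSpec(
            n_mixtures=40, density_scales=(1.02, 1.04, 1.06, 1.08, 1.10)
        ),
    )


def study_samples(basis: dt.TissueBasis) -> dict[str, dt.TissueComposition]:
    """The six samples: basis tissues plus the two bone-mimicking recipes."""
    cortical = dt.hydroxyapatite_water_mixture(
        0.1616, name="cortical_sample"
    )
    spong_sample = dt.mix_by_volume(
        basis.get("cortical_bone"), basis.get("red_marrow"), 0.12,
        name="spongiosa_sample", category="spongiosa",
    )
    return {
        "muscle": basis.get("muscle"),
        "adipose": basis.get("adipose"),
        "spongiosa_sample": spong_sample,
        "cortical_sample": cortical,
        "brain": basis.get("brain"),
        "liver": basis.get("liver"),
    }


def calibration_inserts(basis: dt.TissueBasis) -> list[dt.TissueComposition]:
    """Twelve-insert-style calibration set spanning lung to compact bone."""
    return [t for t in basis.tissues if t.name != "air"]
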