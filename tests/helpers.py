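"""Shared builders for randomised simulation tests."""

import numpy as np

from overrange_kit import ScanProtocol, SimulationSpec, default_layout
from overrange_kit.scan_model import MIN_SLICE_THICKNESS, STRICT_SLICE_THICKNESSES


def random_protocol(rng: np.random.Generator) -> ScanProtocol:
    """A protocol drawn uniformly from the scanner's menus."""
    pitch = 0.5 + 0.05 * int(rng.integers(0, 21))
    collimation = float(rng.choice([12.0, 24.0]))
    min_st = MIN_SLICE_THICKNESS[collimation]
    slices = [s for s in STRICT_SLICE_THICKNESSES if s >= min_st]
    return ScanProtocol(
        pitch=pitch,
        rotation_time=float(rng.choice([0.5, 0.75, 1.0, 1.5])),
        collimation=collimation,
        slice_thickness=float(rng.choice(slices)),
        voi_length=float(rng.uniform(180.0, 320.0)),
    )


def random_spec(
    rng: np.random.Generator, noise_sd: float = 0.0, **kwargs
) -> SimulationSpec:
    prot = random_protocol(rng)
    return SimulationSpec(
        protocol=prot,
        layout=default_layout(prot),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        **kwargs,
    )
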