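"""Acquisition protocol for field-cycling imaging sequences.

A field-cycling acquisition polarises spins at a high field, lets them relax
at a variable low evolution field for a chosen evolution time, and reads the
signal out at a fixed detection field.  The protocol records that grid
together with the spin-echo readout constants and the image geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = ["AcquisitionProtocol", "default_protocol", "DEFAULT_EVOLUTION_FIELDS_MT"]

#: Evolution fields used by the default protocol, in mT.
DEFAULT_EVOLUTION_FIELDS_MT = (2.3, 22.0, 65.8, 200.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Field-cycling sequence grid and geometry.

    Parameters
    ----------
    polarisation_field_mT : float
        Polarisation field B0_P, in mT.
    polarisation_duration_ms : float
        Time spent at the polarisation field, ms.
    evolution_fields_mT : tuple of float
        Evolution fields B0_E probed, in mT.
    evolution_times_ms : mapping field -> tuple of float
        Evolution times t_E at each field, ms, strictly increasing, >= 2 per
        field.
    detection_field_mT : float
        Readout field B0_D, in mT.  Need not dominate the evolution fields.
    echo_time_ms, repetition_time_ms : float
        Spin-echo readout constants.
    matrix_shape : (int, int)
        In-plane image matrix.
    in_plane_resolution_mm, slice_thickness_mm : float
        Voxel geometry (single-slice 2-D acquisition).
    """

    polarisation_field_mT: float
    polarisation_duration_ms: float
    evolution_fields_mT: tuple[float, ...]
    evolution_times_ms: Mapping[float, tuple[float, ...]]
    detection_field_mT: float
    echo_time_ms: float = 16.0
    repetition_time_ms: float = 2000.0
    matrix_shape: tuple[int, int] = (64, 128)
    in_plane_resolution_mm: float = 3.0
    slice_thickness_mm: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "polarisation_field_mT",
            "polarisation_duration_ms",
            "detection_field_mT",
            "echo_time_ms",
            "repetition_time_ms",
            "in_plane_resolution_mm",
            "slice_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.evolution_fields_mT:
            raise ValueError("at least one evolution field is required")
        if len(set(self.evolution_fields_mT)) != len(self.evolution_fields_mT):
            raise ValueError("evolution fields must be unique")
        object.__setattr__(
            self, "evolution_fields_mT", tuple(float(f) for f in self.evolution_fields_mT)
        )
        times = {}
        for f in self.evolution_fields_mT:
            if f <= 0:
                raise ValueError("evolution fields must be positive")
            if f not in self.evolution_times_ms:
                raise ValueError(f"no evolution times for field {f} mT")
            t = tuple(float(x) for x in self.evolution_times_ms[f])
            if len(t) < 2:
                raise ValueError(f"field {f} mT needs >= 2 evolution times")
            if any(x <= 0 for x in t):
                raise ValueError("evolution times must be positive")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("evolution times must be strictly increasing")
            times[f] = t
        object.__setattr__(self, "evolution_times_ms", times)
        if len(self.matrix_shape) != 2 or any(int(n) <= 0 for n in self.matrix_shape):
            raise ValueError("matrix_shape must be a pair of positive integers")
        object.__setattr__(self, "matrix_shape", (int(self.matrix_shape[0]), int(self.matrix_shape[1])))

    def grid(self) -> Iterator[tuple[float, float]]:
        """Iterate (evolution_field_mT, evolution_time_ms) pairs in order."""
        for f in self.evolution_fields_mT:
            for t in self.evolution_times_ms[f]:
                yield (f, t)

    @property
    def n_volumes(self) -> int:
        return sum(len(self.evolution_times_ms[f]) for f in self.evolution_fields_mT)

    def longest_time(self, field_mT: float) -> float:
        return self.evolution_times_ms[field_mT][-1]

    def to_dict(self) -> dict:
        return {
            "polarisation_field_mT": self.polarisation_field_mT,
            "polarisation_duration_ms": self.polarisation_duration_ms,
            "evolution_fields_mT": list(self.evolution_fields_mT),
            "evolution_times_ms": {str(f): list(t) for f, t in self.evolution_times_ms.items()},
            "detection_field_mT": self.detection_field_mT,
            "echo_time_ms": self.echo_time_ms,
            "repetition_time_ms": self.repetition_time_ms,
            "matrix_shape": list(self.matrix_shape),
            "in_plane_resolution_mm": self.in_plane_resolution_mm,
            "slice_thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionProtocol":
        return cls(
            polarisation_field_mT=d["polarisation_field_mT"],
            polarisation_duration_ms=d["polarisation_duration_ms"],
            evolution_fields_mT=tuple(d["evolution_fields_mT"]),
            evolution_times_ms={float(k): tuple(v) for k, v in d["evolution_times_ms"].items()},
            detection_field_mT=d["detection_field_mT"],
            echo_time_ms=d["echo_time_ms"],
            repetition_time_ms=d["repetition_time_ms"],
            matrix_shape=tuple(d["matrix_shape"]),
            in_plane_resolution_mm=d["in_plane_resolution_mm"],
            slice_thickness_mm=d["slice_thickness_mm"],
        )


def _log_spaced_times(t1_slowest_ms: float, n: int = 5) -> tuple[float, ...]:
    """n log-spaced evolution times spanning [0.2, 3] x the slowest T1."""
    import numpy as np

    lo, hi = 0.2 * t1_slowest_ms, 3.0 * t1_slowest_ms
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


def default_protocol(
    tissue_truths: Mapping | None = None,
    matrix_shape: tuple[int, int] = (64, 128),
    n_times: int = 5,
) -> AcquisitionProtocol:
    """Default 4-field x 5-time protocol.

    Evolution times at each field are log-spaced over [0.2, 3] x T1 of the
    slowest (longest-T1) tissue class at that field, so every tissue decay is
    well sampled.  Polarisation at 200 mT for 300 ms, detection at 193 mT,
    TE 16 ms, TR 2000 ms, single 10 mm slice.
    """
    if tissue_truths is None:
        from fci.phantom import default_tissue_truths

        tissue_truths = default_tissue_truths()
    from fci.phantom import truth_r1

    times: dict[float, tuple[float, ...]] = {}
    for f in DEFAULT_EVOLUTION_FIELDS_MT:
        r1_min = min(truth_r1(t, f) for t in tissue_truths.values())
        times[f] = _log_spaced_times(1000.0 / r1_min, n_times)
    return AcquisitionProtocol(
        polarisation_field_mT=200.0,
        polarisation_duration_ms=300.0,
        evolution_fields_mT=DEFAULT_EVOLUTION_FIELDS_MT,
        evolution_times_ms=times,
        detection_field_mT=193.0,
        echo_time_ms=16.0,
        repetition_time_ms=2000.0,
        matrix_shape=matrix_shape,
    )
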