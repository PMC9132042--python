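"""Reduced statistical astrocyte morphology.

A desk-scale stand-in for a full EM-based reconstruction: a spherical soma,
primary branches radiating to the arbor radius as chains of tapering
cylindrical segments, and nanoscopic leaflets (thin short cylinders) attached
along the branches.  Leaflet counts are adjusted so the global
surface-to-volume ratio falls inside a configured target band.  Geometry is
fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MorphologyConfig", "CompartmentGraph", "build_reduced_morphology",
           "MorphologyError"]

SOMA, BRANCH, LEAFLET = 0, 1, 2


class MorphologyError(RuntimeError):
    pass


@dataclass(frozen=True)
class MorphologyConfig:
    n_branches: int = 6
    segments_per_branch: int = 8
    arbor_radius_um: float = 45.0
    soma_diameter_um: float = 8.0
    branch_diameter_um: tuple = (2.0, 0.4)   # proximal -> distal taper
    leaflet_diameter_um: tuple = (0.1, 0.3)  # uniform draw bounds, < 1 um
    leaflet_length_um: tuple = (1.0, 3.0)
    leaflets_per_segment: int = 8
    target_sv_ratio: tuple = (1.8, 12.0)     # um^-1 band for the whole cell
    axial_resistivity_ohm_cm: float = 150.0
    max_retries: int = 5

    def replace(self, **kw) -> "MorphologyConfig":
        return replace(self, **kw)


@dataclass
class CompartmentGraph:
    """Compartment tables plus parent adjacency with axial conductances.

    position um (N,3); diameter/length um; area um^2; volume um^3;
    cls in {SOMA, BRANCH, LEAFLET}; parent index (-1 for soma);
    g_axial uS (conductance to parent); soma_distance um (path length).
    """

    position: np.ndarray
    diameter: np.ndarray
    length: np.ndarray
    area: np.ndarray
    volume: np.ndarray
    cls: np.ndarray
    parent: np.ndarray
    g_axial: np.ndarray
    soma_distance: np.ndarray

    @property
    def n(self) -> int:
        return len(self.diameter)

    @property
    def surface_to_volume(self) -> float:
        return float(self.area.sum() / self.volume.sum())

    def validate(self) -> None:
        if np.any(self.area <= 0) or np.any(self.volume <= 0):
            raise MorphologyError("areas and volumes must be > 0")
        if np.any(self.diameter[self.cls == LEAFLET] >= 1.0):
            raise MorphologyError("leaflet diameters must be < 1 um")
        # connectivity: every non-soma compartment must reach the soma
        for i in range(self.n):
            j, hops = i, 0
            while self.parent[j] >= 0:
                j = self.parent[j]
                hops += 1
                if hops > self.n:
                    raise MorphologyError("parent pointers contain a cycle")
            if self.cls[j] != SOMA:
                raise MorphologyError("graph is not rooted at the soma")


def _axial_g(diameter: float, length: float, ra_ohm_cm: float) -> float:
    """Axial conductance of a cylinder in uS (Ra in ohm cm, geometry in um)."""
    ra_ohm_um = ra_ohm_cm * 1e4
    area = np.pi * diameter**2 / 4.0
    return area / (ra_ohm_um * length) * 1e6


def build_reduced_morphology(
    config: MorphologyConfig | None = None, seed: int = 0
) -> CompartmentGraph:
    cfg = config if config is not None else MorphologyConfig()
    if cfg.n_branches < 1 or cfg.segments_per_branch < 1:
        raise MorphologyError("need at least one branch with one segment")

    for attempt in range(cfg.max_retries):
        rng = np.random.default_rng((seed, attempt))
        g = _generate(cfg, rng)
        lo, hi = cfg.target_sv_ratio
        if lo <= g.surface_to_volume <= hi:
            g.validate()
            return g
    raise MorphologyError(
        f"surface-to-volume target {cfg.target_sv_ratio} unsatisfiable after "
        f"{cfg.max_retries} retries (last value {g.surface_to_volume:.2f})"
    )


def _generate(cfg: MorphologyConfig, rng: np.random.Generator) -> CompartmentGraph:
    pos, diam, length, area, vol, cls, parent, gax, sdist = ([] for _ in range(9))

    d_soma = cfg.soma_diameter_um
    pos.append(np.zeros(3))
    diam.append(d_soma)
    length.append(d_soma)
    area.append(np.pi * d_soma**2)          # sphere
    vol.append(np.pi * d_soma**3 / 6.0)
    cls.append(SOMA)
    parent.append(-1)
    gax.append(0.0)
    sdist.append(0.0)

    seg_len = (cfg.arbor_radius_um - d_soma / 2.0) / cfg.segments_per_branch
    d0, d1 = cfg.branch_diameter_um
    for b in range(cfg.n_branches):
        # quasi-uniform directions on the sphere
        z = rng.uniform(-1, 1)
        phi = rng.uniform(0, 2 * np.pi)
        direction = np.array(
            [np.sqrt(1 - z**2) * np.cos(phi), np.sqrt(1 - z**2) * np.sin(phi), z]
        )
        prev = 0
        for s in range(cfg.segments_per_branch):
            frac = s / max(cfg.segments_per_branch - 1, 1)
            d = d0 + (d1 - d0) * frac
            r0 = d_soma / 2.0 + s * seg_len
            centre = direction * (r0 + seg_len / 2.0)
            idx = len(diam)
            pos.append(centre)
            diam.append(d)
            length.append(seg_len)
            area.append(np.pi * d * seg_len)
            vol.append(np.pi * d**2 / 4.0 * seg_len)
            cls.append(BRANCH)
            parent.append(prev)
            gax.append(_axial_g(d, seg_len, cfg.axial_resistivity_ohm_cm))
            sdist.append(r0 + seg_len / 2.0)

            for _ in range(cfg.leaflets_per_segment):
                dl = rng.uniform(*cfg.leaflet_diameter_um)
                ll = rng.uniform(*cfg.leaflet_length_um)
                offset = rng.normal(scale=0.5, size=3)
                offset -= offset @ direction * direction
                nrm = np.linalg.norm(offset)
                offset = offset / nrm if nrm > 0 else np.array([1.0, 0, 0])
                pos.append(centre + offset * (d / 2.0 + ll / 2.0))
                diam.append(dl)
                length.append(ll)
                area.append(np.pi * dl * ll)
                vol.append(np.pi * dl**2 / 4.0 * ll)
                cls.append(LEAFLET)
                parent.append(idx)
                gax.append(_axial_g(dl, ll, cfg.axial_resistivity_ohm_cm))
                sdist.append(sdist[idx] + ll / 2.0)
            prev = idx

    return CompartmentGraph(
        position=np.array(pos),
        diameter=np.array(diam),
        length=np.array(length),
        area=np.array(area),
        volume=np.array(vol),
        cls=np.array(cls),
        parent=np.array(parent),
        g_axial=np.array(gax),
        soma_distance=np.array(sdist),
    )
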