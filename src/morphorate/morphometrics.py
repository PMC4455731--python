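"""Landmark-based geometric morphometrics.

Reads 2-D landmark configurations from TPS files, superimposes them by
generalized Procrustes analysis (GPA) with optional semilandmark sliding,
and averages superimposed coordinates into per-species (or per-species,
per-sex) consensus shapes.

Conventions
-----------
* Partial Procrustes: every configuration is translated to a zero centroid
  and scaled to unit centroid size; no cos(rho) rescaling afterwards.
* Semilandmarks slide along the chord tangent defined by their two curve
  neighbours, minimizing squared distance to the reference (minimum
  Procrustes distance criterion), interleaved once per GPA iteration.
* The consensus is the plain arithmetic mean of the aligned rows; the final
  frame is canonicalized to the consensus' principal axes so the result does
  not depend on specimen input order or on the original digitizing frame.
"""
from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet", "SliderSpec", "AlignedShapes", "MorphometricsError",
    "read_tps", "write_tps", "centroid_size", "optimal_rotation",
    "slide_semilandmarks", "gpa", "species_consensus",
    "read_slider_spec", "write_shapes_csv", "read_shapes_csv",
]


class MorphometricsError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SliderSpec:
    """Which points slide, and along which chord.

    ``indices[i]`` slides along the unit vector from point ``neighbors[i][0]``
    to point ``neighbors[i][1]``. All indices are 0-based into the point list.
    """
    indices: tuple[int, ...]
    neighbors: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.indices) != len(self.neighbors):
            raise MorphometricsError("one neighbor pair required per slider")
        for i, (a, b) in zip(self.indices, self.neighbors):
            if a == b:
                raise MorphometricsError(
                    f"slider {i}: neighbors must be two distinct points")

    def validate(self, k: int) -> None:
        for i, (a, b) in zip(self.indices, self.neighbors):
            for v in (i, a, b):
                if not 0 <= v < k:
                    raise MorphometricsError(
                        f"slider spec index {v} out of range for k={k}")


@dataclasses.dataclass
class LandmarkSet:
    """One specimen's raw landmark configuration (k points x 2)."""
    specimen_id: str
    coords: np.ndarray
    species: str | None = None
    sex: str = "unknown"
    sliders: SliderSpec | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise MorphometricsError(
                f"{self.specimen_id}: coords must be k x 2")
        k = self.coords.shape[0]
        if k < 3:
            raise MorphometricsError(f"{self.specimen_id}: need k >= 3 points")
        if not np.all(np.isfinite(self.coords)):
            raise MorphometricsError(
                f"{self.specimen_id}: non-finite coordinates")
        uniq = {tuple(p) for p in self.coords}
        if len(uniq) != k:
            raise MorphometricsError(
                f"{self.specimen_id}: coincident landmarks")
        if self.sliders is not None:
            self.sliders.validate(k)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclasses.dataclass
class AlignedShapes:
    """GPA-superimposed shapes: one row of 2k coordinates per configuration."""
    taxa: list[str]
    coords: np.ndarray            # N x 2k, row layout x1,y1,...,xk,yk
    consensus: np.ndarray         # 2k, arithmetic mean of rows
    centroid_sizes: np.ndarray    # N, pre-scaling sizes
    iterations_used: int = 0
    converged: bool = True
    objective_trace: list[float] = dataclasses.field(default_factory=list)
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.coords.shape[1] // 2

    def row_config(self, i: int) -> np.ndarray:
        return self.coords[i].reshape(-1, 2)


# --------------------------------------------------------------------- #
# TPS I/O
# --------------------------------------------------------------------- #

def read_tps(path: str, curve_spec: SliderSpec | None = None,
             metadata: pd.DataFrame | None = None) -> list[LandmarkSet]:
    """Parse a TPS landmark file into one LandmarkSet per specimen.

    Recognized records: ``LM=k`` followed by k "x y" lines, ``ID=`` and
    ``IMAGE=`` (either is used as the specimen id, ID preferred), ``SCALE=``
    (ignored). Specimens with missing/short coordinate blocks are rejected.

    ``metadata``, if given, is indexed by specimen_id with columns
    ``species`` and ``sex``; every specimen must appear in it.
    """
    specimens: list[LandmarkSet] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i, n_rec = 0, 0
    while i < len(lines):
        ln = lines[i]
        if not ln:
            i += 1
            continue
        m = re.match(r"(?i)^LM\s*=\s*(\d+)$", ln)
        if not m:
            raise MorphometricsError(
                f"{path}: expected LM= record at line {i + 1}, got {ln!r}")
        k = int(m.group(1))
        n_rec += 1
        coords = []
        i += 1
        while i < len(lines) and len(coords) < k:
            row = lines[i]
            if re.match(r"(?i)^(LM|ID|IMAGE|SCALE)\s*=", row) or not row:
                break
            parts = row.split()
            if len(parts) != 2:
                raise MorphometricsError(
                    f"{path}: record {n_rec}: bad coordinate line {row!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise MorphometricsError(
                f"{path}: record {n_rec}: LM={k} but only "
                f"{len(coords)} coordinate lines")
        spec_id, image = None, None
        while i < len(lines):
            row = lines[i]
            if re.match(r"(?i)^LM\s*=", row):
                break
            mm = re.match(r"(?i)^(ID|IMAGE|SCALE)\s*=\s*(.*)$", row)
            if mm:
                key, val = mm.group(1).upper(), mm.group(2).strip()
                if key == "ID":
                    spec_id = val
                elif key == "IMAGE":
                    image = val
            elif row:
                raise MorphometricsError(
                    f"{path}: record {n_rec}: unexpected line {row!r}")
            i += 1
        sid = spec_id or image or f"specimen_{n_rec}"
        species, sex = None, "unknown"
        if metadata is not None:
            if sid not in metadata.index:
                raise MorphometricsError(
                    f"{path}: specimen {sid!r} missing from metadata table")
            species = str(metadata.loc[sid, "species"])
            if "sex" in metadata.columns:
                sex = str(metadata.loc[sid, "sex"])
        specimens.append(LandmarkSet(sid, np.array(coords), species=species,
                                     sex=sex, sliders=curve_spec))
    return specimens


def write_tps(specimens: Sequence[LandmarkSet], path: str) -> None:
    with open(path, "w") as fh:
        for sp in specimens:
            fh.write(f"LM={sp.k}\n")
            for x, y in sp.coords:
                fh.write(f"{x:.8f} {y:.8f}\n")
            fh.write(f"ID={sp.specimen_id}\n")


def read_slider_spec(path: str) -> SliderSpec:
    """Curve descriptor: YAML/JSON with 1-based ``sliders: [[prev, pt, next],…]``."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rows = doc["sliders"] if isinstance(doc, dict) else doc
    idx, nb = [], []
    for prev, pt, nxt in rows:
        idx.append(int(pt) - 1)
        nb.append((int(prev) - 1, int(nxt) - 1))
    return SliderSpec(tuple(idx), tuple(nb))


def write_shapes_csv(aligned: AlignedShapes, path: str) -> None:
    k = aligned.k
    cols = [f"{ax}{j + 1}" for j in range(k) for ax in ("x", "y")]
    df = pd.DataFrame(aligned.coords, columns=cols)
    df.insert(0, "taxon", aligned.taxa)
    df.to_csv(path, index=False)


def read_shapes_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index("taxon")


# --------------------------------------------------------------------- #
# Procrustes primitives
# --------------------------------------------------------------------- #

def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances of points from their centroid."""
    config = np.asarray(config, dtype=float)
    c = config - config.mean(axis=0)
    cs = float(np.sqrt((c ** 2).sum()))
    if cs <= 1e-12:
        raise MorphometricsError("degenerate configuration: all points coincide")
    return cs


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    c = config - config.mean(axis=0)
    cs = centroid_size(config)
    return c / cs, cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2-D rotation R minimizing ||source @ R - target||_F.

    The reflection component of the orthogonal Procrustes solution is
    suppressed (det(R) = +1 always).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if np.allclose(source, 0):
        raise MorphometricsError("degenerate (zero) source configuration")
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    return R


def slide_semilandmarks(config: np.ndarray, reference: np.ndarray,
                        sliders: SliderSpec) -> np.ndarray:
    """Displace each semilandmark along its chord tangent toward the reference.

    The tangent at slider p is the unit vector from its previous to its next
    curve neighbour (in ``config``); p moves by the scalar projection of
    (reference_p - p) on that tangent, the 1-D least-squares optimum. Fixed
    landmarks are untouched.
    """
    config = np.asarray(config, float)
    out = config.copy()
    for i, (a, b) in zip(sliders.indices, sliders.neighbors):
        chord = config[b] - config[a]
        norm = np.linalg.norm(chord)
        if norm <= 1e-12:
            raise MorphometricsError(
                f"slider {i}: coincident neighbors {a} and {b}, "
                "tangent undefined")
        tangent = chord / norm
        t = float((reference[i] - config[i]) @ tangent)
        out[i] = config[i] + t * tangent
    return out


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus onto its principal axes.

    Axis signs are fixed so that the point farthest from the centroid has a
    positive first coordinate and det = +1, making the GPA output frame
    independent of specimen ordering and digitizing orientation.
    """
    cov = consensus.T @ consensus
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]                      # major axis first
    far = consensus[np.argmax((consensus ** 2).sum(axis=1))]
    if far @ V[:, 0] < 0:
        V[:, 0] = -V[:, 0]
    if np.linalg.det(V) < 0:
        V[:, 1] = -V[:, 1]
    return V


def gpa(specimens: Sequence[LandmarkSet] | Sequence[np.ndarray],
        tol: float = 1e-10, max_iter: int = 100, slide: bool = False,
        sliders: SliderSpec | None = None,
        project: bool = False) -> AlignedShapes:
    """Generalized Procrustes superimposition of 2-D configurations.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus; when ``slide`` is true the
    semilandmarks are slid against the consensus once per iteration (and the
    configuration re-normalized). Iteration stops when the summed squared
    distance to the consensus improves by less than ``tol``.

    ``project`` applies an orthogonal projection of the aligned rows onto
    the tangent plane at the (unit-normalized) consensus; off by default,
    since downstream rate analysis consumes superimposed coordinates
    directly.
    """
    if len(specimens) < 2:
        raise MorphometricsError("GPA needs at least 2 specimens")
    if isinstance(specimens[0], LandmarkSet):
        ids = [s.specimen_id for s in specimens]
        raw = [s.coords for s in specimens]
        if sliders is None:
            sliders = specimens[0].sliders
        ks = {s.k for s in specimens}
        if len(ks) != 1:
            raise MorphometricsError(f"mixed landmark counts: {sorted(ks)}")
    else:
        ids = [f"config_{i}" for i in range(len(specimens))]
        raw = [np.asarray(s, float) for s in specimens]
    if slide and sliders is None:
        raise MorphometricsError("slide=True requires a slider spec")

    pairs = [_center_scale(c) for c in raw]
    configs = [p[0] for p in pairs]
    sizes = np.array([p[1] for p in pairs])
    k = configs[0].shape[0]

    consensus = configs[0].copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j, cfg in enumerate(configs):
            configs[j] = cfg @ optimal_rotation(cfg, consensus)
        if slide:
            for j, cfg in enumerate(configs):
                slid = slide_semilandmarks(cfg, consensus, sliders)
                slid, _ = _center_scale(slid)
                configs[j] = slid @ optimal_rotation(slid, consensus)
        consensus = np.mean(configs, axis=0)
        obj = float(sum(((c - consensus) ** 2).sum() for c in configs))
        trace.append(obj)
        if it > 1 and trace[-2] - obj < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations "
                      f"(last improvement {trace[-2] - trace[-1]:.3e})")

    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    configs = [c @ R for c in configs]

    coords = np.stack([c.reshape(-1) for c in configs])
    if project:
        c_unit = consensus.reshape(-1)
        c_unit = c_unit / np.linalg.norm(c_unit)
        coords = coords - np.outer(coords @ c_unit - 1.0, c_unit)
        consensus = coords.mean(axis=0).reshape(-1, 2)
    return AlignedShapes(
        taxa=ids, coords=coords, consensus=consensus.reshape(-1),
        centroid_sizes=sizes, iterations_used=it, converged=converged,
        objective_trace=trace,
        metadata={"slide": bool(slide), "tangent_projection": bool(project),
                  "sliding_criterion": "minimum_procrustes_distance",
                  "sliding_interleaved_per_iteration": True,
                  "scale_convention": "partial_procrustes_unit_centroid_size",
                  "tol": tol, "max_iter": max_iter, "k": k})


def species_consensus(aligned: AlignedShapes, species: Sequence[str],
                      sex: Sequence[str] | None = None,
                      by_sex: bool = False,
                      restrict_sex: str | None = None) -> AlignedShapes:
    """Average superimposed rows within species (optionally within sex).

    Group means are re-normalized to unit centroid size. ``restrict_sex``
    keeps only specimens of one sex before averaging; species left with no
    specimen in a requested cell are dropped with a warning (listed in
    ``metadata['dropped']``).
    """
    species = list(species)
    if len(species) != len(aligned.taxa):
        raise MorphometricsError("one species label per aligned row required")
    if (by_sex or restrict_sex) and sex is None:
        raise MorphometricsError("sex labels required for sex-aware consensus")
    sex = list(sex) if sex is not None else ["unknown"] * len(species)

    rows = np.arange(len(species))
    if restrict_sex is not None:
        keep = [i for i in rows if sex[i] == restrict_sex]
        dropped_sp = sorted(set(species) - {species[i] for i in keep})
        rows = np.array(keep, dtype=int)
    else:
        dropped_sp = []
    if by_sex:
        cells = [(species[i], sex[i]) for i in rows]
        labels = sorted(set(cells))
        label_str = [f"{sp}__{sx}" for sp, sx in labels]
        groups = [[rows[j] for j, c in enumerate(cells) if c == lab]
                  for lab in labels]
    else:
        cells = [species[i] for i in rows]
        labels = sorted(set(cells))
        label_str = list(labels)
        groups = [[rows[j] for j, c in enumerate(cells) if c == lab]
                  for lab in labels]
    if dropped_sp:
        warnings.warn(
            f"species with no specimens in requested cell dropped: {dropped_sp}")
    out = np.zeros((len(groups), aligned.coords.shape[1]))
    for g, members in enumerate(groups):
        mean = aligned.coords[members].mean(axis=0).reshape(-1, 2)
        mean -= mean.mean(axis=0)
        out[g] = (mean / centroid_size(mean)).reshape(-1)
    return AlignedShapes(
        taxa=label_str, coords=out, consensus=out.mean(axis=0),
        centroid_sizes=np.ones(len(groups)),
        iterations_used=aligned.iterations_used, converged=aligned.converged,
        metadata={**aligned.metadata, "consensus_of": "species",
                  "by_sex": by_sex, "restrict_sex": restrict_sex,
                  "dropped": dropped_sp})
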