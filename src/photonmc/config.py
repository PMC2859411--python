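"""Structured-text (YAML) run configuration: scene, source, controls.

Schema (all lengths mm, powers W)::

    ambient_n: 1.0
    regions:
      - id: 1
        parent: null            # null marks the root region
        shape: {type: cylinder, center: [0,0,0], radius: 15, height: 30}
        mu_a: 0.0138
        mu_s: 9.1
        g: 0.9
        n: 1.0
    source:
      shape: {type: cylinder, center: [8,0,0], radius: 1, height: 2}
      power: 1.0e-9
    run:                        # optional; CLI flags override
      packets: 100000
      seed: 0
      workers: 1
      voxel_pitch: 0.5
      roulette_threshold_frac: 1.0e-4
      max_events: 1000000

Shape types: ``cylinder`` (center, radius, height; axis along z),
``ellipsoid`` (center, radii), ``sphere`` (center, radius), ``box``
(center, size), ``mesh`` (file: OFF/PLY/STL path, relative to the config).
"""

from __future__ import annotations

import os

import yaml

from .geometry import (Box, Cylinder, Ellipsoid, OpticalProperties, Region,
                       Scene, Sphere, TriangleMesh, load_mesh)
from .transport import SourceSpec

__all__ = ["load_config", "save_config", "scene_to_dict"]


def _shape_from_dict(d: dict, base_dir: str):
    kind = d["type"].lower()
    if kind == "cylinder":
        return Cylinder(center=tuple(d["center"]), radius=float(d["radius"]),
                        height=float(d["height"]))
    if kind == "ellipsoid":
        return Ellipsoid(center=tuple(d["center"]), radii=tuple(d["radii"]))
    if kind == "sphere":
        return Sphere(center=tuple(d["center"]), radius=float(d["radius"]))
    if kind == "box":
        return Box(center=tuple(d["center"]), size=tuple(d["size"]))
    if kind == "mesh":
        path = d["file"]
        if not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        return load_mesh(path)
    raise ValueError(f"unknown shape type {kind!r}")


def _shape_to_dict(shape, mesh_path=None) -> dict:
    if isinstance(shape, Cylinder):
        return {"type": "cylinder", "center": list(map(float, shape.center)),
                "radius": float(shape.radius),
                "height": float(shape.height)}
    if isinstance(shape, Ellipsoid):
        return {"type": "ellipsoid", "center": list(map(float, shape.center)),
                "radii": list(map(float, shape.radii))}
    if isinstance(shape, Sphere):
        return {"type": "sphere", "center": list(map(float, shape.center)),
                "radius": float(shape.radius)}
    if isinstance(shape, Box):
        return {"type": "box", "center": list(map(float, shape.center)),
                "size": list(map(float, shape.size))}
    if isinstance(shape, TriangleMesh):
        if mesh_path is None:
            raise ValueError("mesh shapes need a mesh_path to serialize")
        return {"type": "mesh", "file": mesh_path}
    raise TypeError(f"unknown shape {type(shape)}")


def load_config(path):
    """Read a YAML run config; returns (scene, source, run_options_dict)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))
    strict = bool(doc.get("strict_containment", True))
    regions = []
    for rd in doc["regions"]:
        regions.append(Region(
            id=int(rd["id"]),
            shape=_shape_from_dict(rd["shape"], base),
            props=OpticalProperties(mu_a=float(rd["mu_a"]),
                                    mu_s=float(rd["mu_s"]),
                                    g=float(rd["g"]),
                                    n=float(rd.get("n", 1.0))),
            parent=None if rd.get("parent") is None else int(rd["parent"])))
    scene = Scene(regions, ambient_n=float(doc.get("ambient_n", 1.0)),
                  strict=strict)
    src = None
    if "source" in doc:
        sd = doc["source"]
        src = SourceSpec(shape=_shape_from_dict(sd["shape"], base),
                         total_power=float(sd.get("power", 1e-9)))
    return scene, src, dict(doc.get("run", {}))


def scene_to_dict(scene: Scene, src: SourceSpec | None = None,
                  run: dict | None = None,
                  mesh_paths: dict | None = None) -> dict:
    """Serializable dict for a scene (+source/run); inverse of load."""
    mesh_paths = mesh_paths or {}
    doc = {"ambient_n": float(scene.ambient_n), "regions": []}
    for r in scene.regions:
        doc["regions"].append({
            "id": int(r.id),
            "parent": None if r.parent is None else int(r.parent),
            "shape": _shape_to_dict(r.shape, mesh_paths.get(r.id)),
            "mu_a": float(r.props.mu_a), "mu_s": float(r.props.mu_s),
            "g": float(r.props.g), "n": float(r.props.n)})
    if src is not None:
        doc["source"] = {"shape": _shape_to_dict(src.shape),
                         "power": float(src.total_power)}
    if run:
        doc["run"] = run
    return doc


def save_config(path, scene: Scene, src: SourceSpec | None = None,
                run: dict | None = None, strict_containment: bool = True,
                mesh_paths: dict | None = None):
    doc = scene_to_dict(scene, src, run, mesh_paths)
    if not strict_containment:
        doc["strict_containment"] = False
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
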