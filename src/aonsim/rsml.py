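"""Root System Markup Language (RSML) export.

Writes the root system — primary root, laterals, and nodules/primordia as
annotations — in RSML 1.0.  The simulator tracks positions along axes, not
3-D coordinates, so a simple planar layout is synthesised: the primary root
runs straight down (-z), laterals extend horizontally, alternating sides.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .architecture import PlantTopology


def _polyline(parent: etree._Element, points: list[tuple[float, float, float]]) -> None:
    geom = etree.SubElement(parent, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y, z in points:
        etree.SubElement(poly, "point", x=f"{x:.3f}", y=f"{y:.3f}", z=f"{z:.3f}")


def rsml_tree(plant: PlantTopology) -> etree._ElementTree:
    rsml = etree.Element("rsml", version="1.0")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "mm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "software").text = "aonsim"
    etree.SubElement(meta, "last-modified").text = f"day {plant.day:g}"
    scene = etree.SubElement(rsml, "scene")
    plant_el = etree.SubElement(
        scene, "plant", id=plant.genotype_name or "plant", label=plant.genotype_name
    )

    primary = next(plant.iter_kind("primary_root"))
    p_el = etree.SubElement(
        plant_el, "root", id=primary.id, label="primary_root"
    )
    _polyline(p_el, [(0.0, 0.0, 0.0), (0.0, 0.0, -primary.length)])
    _annotate_nodules(plant, primary.id, p_el)

    for i, lat in enumerate(plant.iter_kind("lateral_root")):
        side = 1.0 if i % 2 == 0 else -1.0
        l_el = etree.SubElement(p_el, "root", id=lat.id, label="lateral_root")
        z = -lat.attach_pos
        _polyline(l_el, [(0.0, 0.0, z), (side * lat.length, 0.0, z)])
        _annotate_nodules(plant, lat.id, l_el)
    return etree.ElementTree(rsml)


def _annotate_nodules(plant: PlantTopology, root_id: str, root_el: etree._Element) -> None:
    nodules = [
        o
        for o in plant.iter_kind("nodule", "nodule_primordium")
        if o.parent_id == root_id
    ]
    if not nodules:
        return
    anns = etree.SubElement(root_el, "annotations")
    for o in nodules:
        ann = etree.SubElement(anns, "annotation", name=o.kind)
        etree.SubElement(ann, "point", x="0", y="0", z=f"{-o.attach_pos:.3f}")
        etree.SubElement(ann, "value").text = o.status


def write_rsml(plant: PlantTopology, path: str | Path) -> Path:
    path = Path(path)
    rsml_tree(plant).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return path
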