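"""Shared fixtures: expensive solves and pipeline products are session-scoped
so the closed-form oracles, conservation checks, and velocimetry tests reuse
one solution instead of re-solving."""

import numpy as np
import pytest

from vesselflow import flow as fl
from vesselflow import imaging, network
from vesselflow.synthetic import (SynthConfig, poiseuille_tube_field,
                                  random_vessel_graph, rasterize_graph)

POISEUILLE = dict(radius=20.0, length=400.0, cells_per_diameter=16,
                  dp=1.0, mu=fl.MU_MEDIA)


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Pressure-driven tube flow along x: field, problem, solution, WSS."""
    from vesselflow.geometry import LUMEN

    field = poiseuille_tube_field(POISEUILLE["radius"], POISEUILLE["length"],
                                  POISEUILLE["cells_per_diameter"], axis=0)
    props = fl.MaterialProps.control()
    bcs = fl.BoundaryConditions(
        pressures={"inlet": {LUMEN: POISEUILLE["dp"]},
                   "outlet": {LUMEN: 0.0}})
    problem = fl.assemble_problem(field, props, bcs)
    solution = fl.solve_flow(problem)
    wss = fl.wall_shear_stress(solution, field, props)
    return {"field": field, "props": props, "bcs": bcs, "problem": problem,
            "solution": solution, "wss": wss, **POISEUILLE}


@pytest.fixture(scope="session")
def velocimetry_tube():
    """Long sparse tube (~130 um/s mean flow) for bead velocimetry."""
    from vesselflow.geometry import LUMEN

    field = poiseuille_tube_field(20.0, 1200.0, 8, axis=0)
    bcs = fl.BoundaryConditions(pressures={"inlet": {LUMEN: 3.0},
                                           "outlet": {LUMEN: 0.0}})
    return fl.solve_flow(fl.assemble_problem(
        field, fl.MaterialProps.control(), bcs))


@pytest.fixture(scope="session")
def extraction_roundtrip():
    """Synthetic 20-link network -> noisy stack -> mask -> measured graph."""
    cfg = SynthConfig(seed=1)
    truth_graph = random_vessel_graph(cfg)
    stack, truth_mask = rasterize_graph(truth_graph, spacing=1.0, config=cfg)
    smoothed = imaging.gaussian_smooth(stack, 1.0)
    mask = imaging.clean_mask(imaging.binarize(smoothed, method="adaptive"),
                              500)
    skeleton = network.skeletonize(mask)
    graph = network.skeleton_to_graph(skeleton)
    network.measure_links(graph)
    graph = network.subdivide_tortuous(graph)
    network.estimate_radii(graph, mask)
    return {"config": cfg, "truth_graph": truth_graph, "stack": stack,
            "truth_mask": truth_mask, "mask": mask, "skeleton": skeleton,
            "graph": graph}


@pytest.fixture(scope="session")
def phantom_scenarios():
    """Two-channel grid phantom solved for the control and IL-1beta
    parameter sets, plus the equal-pressure treated solve."""
    from vesselflow.geometry import LUMEN
    from vesselflow.synthetic import two_channel_phantom

    graph, field = two_channel_phantom()
    out = {"graph": graph, "field": field}
    cases = {
        "control": (fl.MaterialProps.control(),
                    fl.BoundaryConditions.control(), fl.P_VESSEL_CONTROL),
        "il1b_same_p": (fl.MaterialProps.il1b(),
                        fl.BoundaryConditions.control(), fl.P_VESSEL_CONTROL),
        "il1b": (fl.MaterialProps.il1b(),
                 fl.BoundaryConditions.treated(), fl.P_VESSEL_TREATED),
    }
    lum = field.labels == LUMEN
    xfrac = (np.arange(field.shape[0])[:, None, None]
             * np.ones(field.shape)) / field.shape[0]
    for name, (props, bcs, p_ref) in cases.items():
        problem = fl.assemble_problem(field, props, bcs)
        sol = fl.solve_flow(problem)
        wss = fl.wall_shear_stress(sol, field, props)
        stats = fl.link_statistics(sol, field, graph, wss)
        per_face, imbalance = fl.boundary_flux_report(problem, sol)
        speed = np.linalg.norm(sol.cell_velocity(), axis=-1)
        out[name] = {
            "solution": sol, "wss": wss, "stats": stats,
            "leakage": sum(s.leakage for s in stats),
            "outlet_discharge": per_face["x+"],
            "imbalance": imbalance,
            "mean_wss": wss.mean,
            "distal_velocity": float(speed[lum & (xfrac > 0.75)].mean()),
            "conductance": per_face["x+"] / p_ref,
        }
    return out
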