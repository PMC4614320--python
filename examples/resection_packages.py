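"""Resection injury: removing a fixed defect in packages.

A resection removes m nodes in n_p equal contiguous packages, one package
every IRT steps — the surgical middle ground between immediate (n_p=1 or
IRT=0) and fully gradual (n_p=m) injury.  This sweeps package count and IRT
on the scaled three-layer model and prints the mean MAoD surface.
"""

from lesionlab import EtaPolicy, ThreeLayerParams, resection_grid

params = ThreeLayerParams().scaled()
grid = resection_grid(
    params,
    EtaPolicy.fixed(),
    m=16,
    np_values=[1, 2, 4, 8],
    irt_values=[0, 25, 50],
    n_seeds=3,
    master_seed=0,
)

print("mean MAoD for a 16-node resection (rows: n_p packages, cols: IRT):")
print(grid.summary_frame().pivot(index="n_p", columns="irt", values="mean_maod"))
print()
print("Finer division (more packages) and longer pauses between packages both")
print("lower the worst disability the network suffers; n_p=1 or IRT=0 is an")
print("immediate injury and anchors the worst corner of the surface.")
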