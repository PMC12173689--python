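"""Characterise mesh inserts: pore-size and Weibull-parameter regressions.

Fits the log-log mesh/pore regression from the three measured meshes,
extrapolates the pore area of the unmeasurably fine 686 mesh, fits the
three pore→Weibull-parameter regressions, and predicts the transfer
parameters of the 508 mesh used in the metabolism studies.
"""

import meshivive as mi
from meshivive import reference as ref

pairs = list(ref.MEASURED_PORE_AREAS.items())
reg = mi.fit_pore_size_regression(pairs)
print(f"log10(pore) = {reg.slope:.3f} * log10(mesh) + {reg.intercept:.3f}"
      f"   (R^2 = {reg.r_squared:.3f})")
print(f"predicted 686-mesh pore area: {mi.predict_pore_size(reg, 686):.2f} um^2")

rows = [(ref.WEIBULL_TRAINING_PORES[m], w.a_max, w.alpha, w.beta)
        for m, w in ref.WEIBULL_BY_MESH.items()]
regs = mi.fit_weibull_param_regressions(rows)
print(f"\na_max = {regs.a_max_fit.a:.5f} * exp({regs.a_max_fit.b:.6f} * pore)"
      f"   (R^2 = {regs.a_max_fit.r_squared:.3f})")
print(f"alpha = {regs.alpha_fit.a:.3f} * exp({regs.alpha_fit.b:.6f} * pore)"
      f"   (R^2 = {regs.alpha_fit.r_squared:.3f})")
print(f"beta  = -{regs.beta_fit.a:.3f} * pore^{regs.beta_fit.b:.3f}"
      f"   (R^2 = {regs.beta_fit.r_squared:.4f})")

wp = mi.predict_weibull_params(regs, 400.0)
print(f"\n508 mesh (400 um^2): a_max={wp.a_max:.4f} 1/h, "
      f"alpha={wp.alpha:.3f} h, beta={wp.beta:.2f}")
print("These are the fixed diffusion parameters of the metabolism studies;")
print("a coarser mesh (larger pore) transfers faster and equilibrates sooner.")
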