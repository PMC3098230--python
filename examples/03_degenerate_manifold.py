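"""The critical case b = c: a continuum of steady states.

At the degenerate point the interior fixed points merge into the curve
(1+b*x)(1+b*y) = a/d.  Every point on it is a steady state with one zero
eigenvalue (no force along the curve) and one negative eigenvalue pulling
trajectories onto it; the attraction is strongest at the symmetric point.
"""

from fatecircuit import GenericParams, lambda_min, manifold_eigenvalues, sample_manifold
from fatecircuit.degenerate_manifold import x_max

p = GenericParams(a=1.0, f=1.0, b=0.5, c=0.5, d=0.5)

print(f"manifold spans x in [0, {x_max(p)}]; endpoints are the committed states")
print(" x      y       lambda    mu")
for pt in sample_manifold(p, 9):
    print(f"{pt.x:5.3f}  {pt.y:5.3f}   {pt.lam:+.4f}   {pt.mu:+.1e}")

x_star, lam_star = lambda_min(p)
print(f"\nlambda has its interior minimum {lam_star:.5f} at x* = {x_star:.5f} "
      f"(= 2*(sqrt(2)-1), the symmetric point)")
print("endpoint lambda:", manifold_eigenvalues(0.0, p)[0])
# Under noise the lambda-minimum is the most strongly attracting stretch of
# the manifold: the model's picture of the indeterminate progenitor state,
# with intermediate, anti-correlated levels of the two factors.
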