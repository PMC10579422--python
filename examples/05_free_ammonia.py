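"""Free-ammonia speciation across digester operating points.

Unionized NH3 — not total ammonia — is what inhibits methanogens. The
fraction rises steeply with pH and temperature, which is why a thermophilic
digester at pH 8.3 can be ammonia-stressed at a total ammonia level that a
mesophilic one at pH 7.5 tolerates easily.
"""

from syntherm import free_ammonia

print(f"{'TAN g N/L':>10s} {'pH':>5s} {'T degC':>7s} {'f(NH3)':>8s} "
      f"{'g N/L':>7s} {'g NH3/L':>8s}")
for tan, ph, t_c in [
    (3.0, 7.5, 37.0),   # mesophilic, moderate pH
    (3.0, 8.1, 52.0),   # thermophilic enrichment reactor
    (3.0, 8.3, 52.0),
    (3.0, 8.5, 52.0),   # thermophilic batch assay
]:
    res = free_ammonia(tan, ph, t_c + 273.15)
    print(f"{tan:10.1f} {ph:5.1f} {t_c:7.1f} {res.fraction_unionized:8.3f} "
          f"{res.nh3_n:7.2f} {res.nh3_mass:8.2f}")

print(
    "\nAt 52 degC and pH 8.3-8.5 roughly 40-55% of the ammonia pool is"
    "\nunionized: ~1.2-1.6 g N/L free ammonia from 3 g N/L total, far above"
    "\ncommon inhibition thresholds. Both the N-mass and NH3-mass bases are"
    "\nreported because the literature rarely states which it uses."
)
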