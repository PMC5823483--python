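"""Compare resolution uniformity across the field of view.

Runs the full battery: bar phantoms at 6, 47 and 127 mm from the isocenter
are acquired through the distance-dependent blur model and reconstructed
with plain FBP, sharpened FBP (unsharp masking) and the 11-subband
deconvolution.  The bar-pattern MTF at 5 lp/cm is tabulated per offset and
summarized by the spread statistic (max − min)/mean: the subband method
should hold its MTF nearly constant across the FOV while restoring it well
above the FBP baseline.

Writes a JSON report and a PNG plot per method into ./scratch/.
"""

from pathlib import Path

from subbandct.pipeline import run_uniformity_battery

result = run_uniformity_battery(
    offsets_mm=(6.0, 47.0, 127.0),
    frequency_lp_cm=5.0,
    methods=("fbp", "sharp_fbp", "subband"),
)

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)
print("MTF at 5 lp/cm per offset (noiseless battery):")
for method, report in result.reports.items():
    values = "  ".join(
        f"{off:5.0f} mm: {v:.3f}" for off, v in zip(report.offsets_mm, report.mtf)
    )
    print(f"  {method:10s} {values}   spread {report.spread:.3f}")
    (out_dir / f"uniformity_{method}.json").write_text(report.to_json())
    report.plot(out_dir / f"uniformity_{method}.png")

sub = result.reports["subband"].spread
base = result.reports["fbp"].spread
print(f"\nsubband spread / fbp spread = {sub / base:.2f} "
      "(smaller means more uniform resolution across the FOV)")
print(f"reports and plots written to {out_dir}/")
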