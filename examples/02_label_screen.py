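"""From raw plate readouts to the labeled dataset D = {(c_i, d_i, y_i)}.

Normalizes raw well signals to the plate median (beta = signal / median),
applies the threshold rule (increase if beta >= 1.3, decrease if beta <=
0.7, no change between), collapses replicate (compound, dose) rows to their
median beta, and shows the binary relaxation used for the easier
positive/negative variant of the task.
"""

from phagoscreen import assign_class, build_dataset, normalize_plate, relax_binary
from phagoscreen.screenlab import ScreenRecord

# one small plate of raw fluorescence values
plate = [("A1", 980.0), ("A2", 1510.0), ("A3", 640.0), ("A4", 1010.0), ("A5", 1350.0)]
normalized = normalize_plate(plate)
for well, beta in normalized:
    print(f"well {well}: beta = {beta:.3f} -> {assign_class(beta)}")

# replicate measurements of the same compound+dose collapse to the median
records = [
    ScreenRecord("cpd-1", "Cc1ccccc1CCc1ccccc1", 5.56, beta=0.55),
    ScreenRecord("cpd-1", "Cc1ccccc1CCc1ccccc1", 5.56, beta=0.65),
    ScreenRecord("cpd-1", "Cc1ccccc1CCc1ccccc1", 5.56, beta=0.80),
    ScreenRecord("cpd-2", "COc1ccc(CN)cc1", 5.56, beta=1.42),
    ScreenRecord("cpd-3", "CCOC(=O)c1ccccc1", 5.56, beta=1.05),
]
dataset = build_dataset(records)
print(f"\n{len(records)} raw rows -> {len(dataset)} unique compound-dose records")
for r in dataset.records:
    print(f"  {r.compound_id}: beta {r.beta:.3f} -> {r.label}")

binary = relax_binary(dataset)
print(f"\nbinary relaxation (decrease = positive): {binary.class_counts()}")
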