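"""Leave-one-out benchmark of both detectors, with information transfer rate.

On a fixed-seed synthetic session (20 trials per target, 0.5 s epochs,
-5 dB narrowband SNR) every trial takes a turn as the test signal.  The
command time is 0.5 s flicker + 0.5 s rest = 1.0 s.  Printed per detector:
LOOCV accuracy, the ITR in bit/s (log2(3) ~ 1.585 bit/s is the ceiling for
3 targets at this command rate), and the confusion matrix.
"""

from itdma import command_time, generate_dataset, loocv_accuracy
from itdma.sim import default_mixing

training, _ = generate_dataset(
    default_mixing(snr_db=-5.0), n_t=20, duration_s=0.5, seed=4
)
t0 = command_time(flicker_s=0.5, rest_s=0.5)

for algorithm in ("itdma", "trca"):
    res = loocv_accuracy(training, algorithm=algorithm, t0_s=t0)
    print(f"{algorithm}: accuracy {res.accuracy:.3f} "
          f"({res.n_correct}/{res.n_total}), ITR {res.itr_bits_per_s:.2f} bit/s")
    print("confusion (rows = true target):")
    print(res.confusion, "\n")
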