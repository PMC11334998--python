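"""Recover heart rate from carrier-interruption audio.

A transmitter emits a continuous tone gated off for ~15 ms at each
heartbeat.  The detector finds envelope dips against a rolling median
threshold and aggregates inter-beat intervals to b.p.m. per minute.
"""

import numpy as np

from hrenergetics import hrsignal, synth

schedule = synth.BeatSchedule.constant(bpm=300, duration_s=120.0)
audio = synth.gen_carrier_audio(schedule, snr_db=20.0, seed=2)

events = hrsignal.detect_beats(hrsignal.envelope(audio), audio.sample_rate)
series = hrsignal.extract_heart_rate(audio)

errors_ms = [1000 * np.min(np.abs(events.times - t)) for t in schedule.beat_times]
print(f"true beats: {len(schedule.beat_times)}, detected: {len(events)}")
print(f"worst timing error: {max(errors_ms):.2f} ms")
print(series.data)
# each fully covered minute reads 300 b.p.m. with quality 1.0: every
# inter-beat interval was physiologically plausible
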