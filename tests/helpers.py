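import numpy as np
import pandas as pd

from ethotrack.core import Trajectory


def path_to_trajectory(path, mm_per_px=0.1, roi_index=0):
    """Lift a generator FlyPath into a Trajectory (exact positions, no imaging)."""
    df = pd.DataFrame(
        {
            "t": path.t,
            "x": path.x_mm / mm_per_px,
            "y": path.y_mm / mm_per_px,
            "x_mm": path.x_mm,
            "w": 25.0,
            "h": 10.0,
            "phi": 0.0,
            "is_inferred": False,
        }
    )
    return Trajectory(df, roi_index, mm_per_px)


def window_max_velocities(path, window_s=10.0, body_length_mm=2.5):
    """Independent oracle: per-window max corrected velocity from positions."""
    disp = np.hypot(np.diff(path.x_mm), np.diff(path.y_mm))
    dt = np.diff(path.t)
    v = (disp / body_length_mm) * (path.dt_nominal / dt)
    idx = np.floor((path.t[1:] - path.t[0]) / window_s).astype(int)
    n_win = int((path.t[-1] - path.t[0]) // window_s)
    return np.array([v[idx == k].max() for k in range(n_win)])
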