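"""Versioned parameter presets for the stimulation protocols.

The points are chosen from the analytic phase diagram (see phase module):

- ``CYLINDER_SHALLOW``: bump size just below the cylinder onset, so the
  admissible x_phi range is narrow and moderate stimulus steps flip the
  bump offset -- the working point for the delayed shortest-path task.
- ``CYLINDER_DEEP``: bump much smaller than the phi interval, so the active
  subsets at the two ends of the x_phi range barely overlap -- the working
  point for dynamical pattern separation.
- ``DOUBLE_RING``: uncorrelated maps just above the Turing boundary.
- ``SINGLE_RING``: correlated maps at moderate coupling.
- ``MORPH_CYLINDER``: weakly correlated pair in the cylinder regime, used by
  the slow-morph comparison against the morph-equivalent storage at the same
  coupling and inhibition.
"""

from .meanfield import ModelParams, MORPH_EQUIV_DISTANCE

PRESET_VERSION = 1

SINGLE_RING = ModelParams(d=0.3, J_mod=3.0, J_inh=4.0)
DOUBLE_RING = ModelParams(d=1.0, J_mod=2.6, J_inh=4.0)
CYLINDER_SHALLOW = ModelParams(d=0.8, J_mod=10.0, J_inh=10.0)
CYLINDER_DEEP = ModelParams(d=0.8, J_mod=55.0, J_inh=100.0)
TASK_CYLINDER = ModelParams(d=0.5, J_mod=22.0, J_inh=35.0)
MORPH_CYLINDER = ModelParams(d=0.6, J_mod=30.0, J_inh=50.0)
MORPH_EQUIV_CYLINDER = ModelParams(d=MORPH_EQUIV_DISTANCE, J_mod=30.0, J_inh=50.0)

#: Distance for coupling-strength scans that traverse double ring ->
#: single ring -> cylinder (the mu branch exists only at weak coupling
#: and low correlation).
SCAN_DISTANCE = 0.95

#: Default protocol knobs (tracking regime: the bump follows the moving
#: input with a constant delay instead of slipping).
MOVING_INPUT_EPS = 0.15
MOVING_PERIOD_TAU = 300.0  # input revolution time, in units of tau

#: Delayed-discrimination task: stimuli must be strong and long enough for
#: the bump to complete travel along arcs up to pi within one presentation.
TASK_EPS = 0.4
TASK_DURATIONS_TAU = (80.0, 30.0, 80.0)  # stimulus-1, delay, stimulus-2
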