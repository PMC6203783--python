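"""Turner 2004 1x1 interior-loop free energies (kcal/mol, 37 C).

INT11[(pair1, pair2, x, y)] for the loop 5'-P x Q-3' / 3'-p y q-5' with
pair1 = Pp and pair2 = qQ (the second closing pair read from the far side).
"""

INT11 = {
    ('AU', 'AU', 'A', 'A'): 1.9,
    ('AU', 'AU', 'A', 'C'): 1.9,
    ('AU', 'AU', 'A', 'G'): 1.9,
    ('AU', 'AU', 'A', 'U'): 1.9,
    ('AU', 'AU', 'C', 'A'): 1.9,
    ('AU', 'AU', 'C', 'C'): 1.9,
    ('AU', 'AU', 'C', 'G'): 1.9,
    ('AU', 'AU', 'C', 'U'): 1.9,
    ('AU', 'AU', 'G', 'A'): 1.9,
    ('AU', 'AU', 'G', 'C'): 1.9,
    ('AU', 'AU', 'G', 'G'): -0.7,
    ('AU', 'AU', 'G', 'U'): 1.9,
    ('AU', 'AU', 'U', 'A'): 1.9,
    ('AU', 'AU', 'U', 'C'): 1.9,
    ('AU', 'AU', 'U', 'G'): 1.9,
    ('AU', 'AU', 'U', 'U'): 1.2,
    ('AU', 'CG', 'A', 'A'): 1.2,
    ('AU', 'CG', 'A', 'C'): 1.2,
    ('AU', 'CG', 'A', 'G'): 1.2,
    ('AU', 'CG', 'A', 'U'): 1.2,
    ('AU', 'CG', 'C', 'A'): 1.2,
    ('AU', 'CG', 'C', 'C'): 1.2,
    ('AU', 'CG', 'C', 'G'): 1.2,
    ('AU', 'CG', 'C', 'U'): 1.2,
    ('AU', 'CG', 'G', 'A'): 1.2,
    ('AU', 'CG', 'G', 'C'): 1.2,
    ('AU', 'CG', 'G', 'G'): -1.4,
    ('AU', 'CG', 'G', 'U'): 1.2,
    ('AU', 'CG', 'U', 'A'): 1.2,
    ('AU', 'CG', 'U', 'C'): 1.2,
    ('AU', 'CG', 'U', 'G'): 1.2,
    ('AU', 'CG', 'U', 'U'): 0.8,
    ('AU', 'GC', 'A', 'A'): 1.2,
    ('AU', 'GC', 'A', 'C'): 1.2,
    ('AU', 'GC', 'A', 'G'): 1.2,
    ('AU', 'GC', 'A', 'U'): 1.2,
    ('AU', 'GC', 'C', 'A'): 1.2,
    ('AU', 'GC', 'C', 'C'): 1.2,
    ('AU', 'GC', 'C', 'G'): 1.2,
    ('AU', 'GC', 'C', 'U'): 1.2,
    ('AU', 'GC', 'G', 'A'): 1.2,
    ('AU', 'GC', 'G', 'C'): 1.2,
    ('AU', 'GC', 'G', 'G'): -1.4,
    ('AU', 'GC', 'G', 'U'): 1.2,
    ('AU', 'GC', 'U', 'A'): 1.2,
    ('AU', 'GC', 'U', 'C'): 1.2,
    ('AU', 'GC', 'U', 'G'): 1.2,
    ('AU', 'GC', 'U', 'U'): 0.8,
    ('AU', 'GU', 'A', 'A'): 1.9,
    ('AU', 'GU', 'A', 'C'): 1.9,
    ('AU', 'GU', 'A', 'G'): 1.9,
    ('AU', 'GU', 'A', 'U'): 1.9,
    ('AU', 'GU', 'C', 'A'): 1.9,
    ('AU', 'GU', 'C', 'C'): 1.9,
    ('AU', 'GU', 'C', 'G'): 1.9,
    ('AU', 'GU', 'C', 'U'): 1.9,
    ('AU', 'GU', 'G', 'A'): 1.9,
    ('AU', 'GU', 'G', 'C'): 1.9,
    ('AU', 'GU', 'G', 'G'): -0.7,
    ('AU', 'GU', 'G', 'U'): 1.9,
    ('AU', 'GU', 'U', 'A'): 1.9,
    ('AU', 'GU', 'U', 'C'): 1.9,
    ('AU', 'GU', 'U', 'G'): 1.9,
    ('AU', 'GU', 'U', 'U'): 1.2,
    ('AU', 'UA', 'A', 'A'): 1.9,
    ('AU', 'UA', 'A', 'C'): 1.9,
    ('AU', 'UA', 'A', 'G'): 1.9,
    ('AU', 'UA', 'A', 'U'): 1.9,
    ('AU', 'UA', 'C', 'A'): 1.9,
    ('AU', 'UA', 'C', 'C'): 1.9,
    ('AU', 'UA', 'C', 'G'): 1.9,
    ('AU', 'UA', 'C', 'U'): 1.9,
    ('AU', 'UA', 'G', 'A'): 1.9,
    ('AU', 'UA', 'G', 'C'): 1.9,
    ('AU', 'UA', 'G', 'G'): -0.7,
    ('AU', 'UA', 'G', 'U'): 1.9,
    ('AU', 'UA', 'U', 'A'): 1.9,
    ('AU', 'UA', 'U', 'C'): 1.9,
    ('AU', 'UA', 'U', 'G'): 1.9,
    ('AU', 'UA', 'U', 'U'): 1.5,
    ('AU', 'UG', 'A', 'A'): 1.9,
    ('AU', 'UG', 'A', 'C'): 1.9,
    ('AU', 'UG', 'A', 'G'): 1.9,
    ('AU', 'UG', 'A', 'U'): 1.9,
    ('AU', 'UG', 'C', 'A'): 1.9,
    ('AU', 'UG', 'C', 'C'): 1.9,
    ('AU', 'UG', 'C', 'G'): 1.9,
    ('AU', 'UG', 'C', 'U'): 1.9,
    ('AU', 'UG', 'G', 'A'): 1.9,
    ('AU', 'UG', 'G', 'C'): 1.9,
    ('AU', 'UG', 'G', 'G'): -0.7,
    ('AU', 'UG', 'G', 'U'): 1.9,
    ('AU', 'UG', 'U', 'A'): 1.9,
    ('AU', 'UG', 'U', 'C'): 1.9,
    ('AU', 'UG', 'U', 'G'): 1.9,
    ('AU', 'UG', 'U', 'U'): 1.6,
    ('CG', 'AU', 'A', 'A'): 1.2,
    ('CG', 'AU', 'A', 'C'): 1.2,
    ('CG', 'AU', 'A', 'G'): 1.2,
    ('CG', 'AU', 'A', 'U'): 1.2,
    ('CG', 'AU', 'C', 'A'): 1.2,
    ('CG', 'AU', 'C', 'C'): 1.2,
    ('CG', 'AU', 'C', 'G'): 1.2,
    ('CG', 'AU', 'C', 'U'): 1.2,
    ('CG', 'AU', 'G', 'A'): 1.2,
    ('CG', 'AU', 'G', 'C'): 1.2,
    ('CG', 'AU', 'G', 'G'): -1.4,
    ('CG', 'AU', 'G', 'U'): 1.2,
    ('CG', 'AU', 'U', 'A'): 1.2,
    ('CG', 'AU', 'U', 'C'): 1.2,
    ('CG', 'AU', 'U', 'G'): 1.2,
    ('CG', 'AU', 'U', 'U'): 0.8,
    ('CG', 'CG', 'A', 'A'): 0.9,
    ('CG', 'CG', 'A', 'C'): 0.5,
    ('CG', 'CG', 'A', 'G'): 0.5,
    ('CG', 'CG', 'A', 'U'): 0.5,
    ('CG', 'CG', 'C', 'A'): 0.5,
    ('CG', 'CG', 'C', 'C'): 0.5,
    ('CG', 'CG', 'C', 'G'): 0.5,
    ('CG', 'CG', 'C', 'U'): 0.5,
    ('CG', 'CG', 'G', 'A'): 0.5,
    ('CG', 'CG', 'G', 'C'): 0.5,
    ('CG', 'CG', 'G', 'G'): -1.4,
    ('CG', 'CG', 'G', 'U'): 0.5,
    ('CG', 'CG', 'U', 'A'): 0.5,
    ('CG', 'CG', 'U', 'C'): 0.5,
    ('CG', 'CG', 'U', 'G'): 0.5,
    ('CG', 'CG', 'U', 'U'): 0.4,
    ('CG', 'GC', 'A', 'A'): 0.9,
    ('CG', 'GC', 'A', 'C'): -0.4,
    ('CG', 'GC', 'A', 'G'): 0.5,
    ('CG', 'GC', 'A', 'U'): 0.5,
    ('CG', 'GC', 'C', 'A'): 0.3,
    ('CG', 'GC', 'C', 'C'): 0.5,
    ('CG', 'GC', 'C', 'G'): 0.5,
    ('CG', 'GC', 'C', 'U'): 0.6,
    ('CG', 'GC', 'G', 'A'): -0.1,
    ('CG', 'GC', 'G', 'C'): 0.5,
    ('CG', 'GC', 'G', 'G'): -2.2,
    ('CG', 'GC', 'G', 'U'): 0.5,
    ('CG', 'GC', 'U', 'A'): 0.5,
    ('CG', 'GC', 'U', 'C'): 0.0,
    ('CG', 'GC', 'U', 'G'): 0.5,
    ('CG', 'GC', 'U', 'U'): -0.1,
    ('CG', 'GU', 'A', 'A'): 0.6,
    ('CG', 'GU', 'A', 'C'): 0.5,
    ('CG', 'GU', 'A', 'G'): 1.2,
    ('CG', 'GU', 'A', 'U'): 1.2,
    ('CG', 'GU', 'C', 'A'): 1.2,
    ('CG', 'GU', 'C', 'C'): 1.2,
    ('CG', 'GU', 'C', 'G'): 1.2,
    ('CG', 'GU', 'C', 'U'): 1.2,
    ('CG', 'GU', 'G', 'A'): -0.2,
    ('CG', 'GU', 'G', 'C'): 1.2,
    ('CG', 'GU', 'G', 'G'): -1.4,
    ('CG', 'GU', 'G', 'U'): 1.2,
    ('CG', 'GU', 'U', 'A'): 1.2,
    ('CG', 'GU', 'U', 'C'): 1.0,
    ('CG', 'GU', 'U', 'G'): 1.2,
    ('CG', 'GU', 'U', 'U'): 1.1,
    ('CG', 'UA', 'A', 'A'): 1.2,
    ('CG', 'UA', 'A', 'C'): 1.2,
    ('CG', 'UA', 'A', 'G'): 1.2,
    ('CG', 'UA', 'A', 'U'): 1.2,
    ('CG', 'UA', 'C', 'A'): 1.2,
    ('CG', 'UA', 'C', 'C'): 1.2,
    ('CG', 'UA', 'C', 'G'): 1.2,
    ('CG', 'UA', 'C', 'U'): 1.2,
    ('CG', 'UA', 'G', 'A'): 1.2,
    ('CG', 'UA', 'G', 'C'): 1.2,
    ('CG', 'UA', 'G', 'G'): -1.4,
    ('CG', 'UA', 'G', 'U'): 1.2,
    ('CG', 'UA', 'U', 'A'): 1.2,
    ('CG', 'UA', 'U', 'C'): 1.2,
    ('CG', 'UA', 'U', 'G'): 1.2,
    ('CG', 'UA', 'U', 'U'): 1.2,
    ('CG', 'UG', 'A', 'A'): 2.2,
    ('CG', 'UG', 'A', 'C'): 1.3,
    ('CG', 'UG', 'A', 'G'): 1.2,
    ('CG', 'UG', 'A', 'U'): 1.2,
    ('CG', 'UG', 'C', 'A'): 1.2,
    ('CG', 'UG', 'C', 'C'): 1.7,
    ('CG', 'UG', 'C', 'G'): 1.2,
    ('CG', 'UG', 'C', 'U'): 1.2,
    ('CG', 'UG', 'G', 'A'): 1.2,
    ('CG', 'UG', 'G', 'C'): 1.2,
    ('CG', 'UG', 'G', 'G'): -1.4,
    ('CG', 'UG', 'G', 'U'): 1.2,
    ('CG', 'UG', 'U', 'A'): 1.2,
    ('CG', 'UG', 'U', 'C'): 1.2,
    ('CG', 'UG', 'U', 'G'): 1.2,
    ('CG', 'UG', 'U', 'U'): 1.1,
    ('GC', 'AU', 'A', 'A'): 1.2,
    ('GC', 'AU', 'A', 'C'): 1.2,
    ('GC', 'AU', 'A', 'G'): 1.2,
    ('GC', 'AU', 'A', 'U'): 1.2,
    ('GC', 'AU', 'C', 'A'): 1.2,
    ('GC', 'AU', 'C', 'C'): 1.2,
    ('GC', 'AU', 'C', 'G'): 1.2,
    ('GC', 'AU', 'C', 'U'): 1.2,
    ('GC', 'AU', 'G', 'A'): 1.2,
    ('GC', 'AU', 'G', 'C'): 1.2,
    ('GC', 'AU', 'G', 'G'): -1.4,
    ('GC', 'AU', 'G', 'U'): 1.2,
    ('GC', 'AU', 'U', 'A'): 1.2,
    ('GC', 'AU', 'U', 'C'): 1.2,
    ('GC', 'AU', 'U', 'G'): 1.2,
    ('GC', 'AU', 'U', 'U'): 0.8,
    ('GC', 'CG', 'A', 'A'): 0.9,
    ('GC', 'CG', 'A', 'C'): 0.3,
    ('GC', 'CG', 'A', 'G'): -0.1,
    ('GC', 'CG', 'A', 'U'): 0.5,
    ('GC', 'CG', 'C', 'A'): -0.4,
    ('GC', 'CG', 'C', 'C'): 0.5,
    ('GC', 'CG', 'C', 'G'): 0.5,
    ('GC', 'CG', 'C', 'U'): 0.0,
    ('GC', 'CG', 'G', 'A'): 0.5,
    ('GC', 'CG', 'G', 'C'): 0.5,
    ('GC', 'CG', 'G', 'G'): -2.2,
    ('GC', 'CG', 'G', 'U'): 0.5,
    ('GC', 'CG', 'U', 'A'): 0.5,
    ('GC', 'CG', 'U', 'C'): 0.6,
    ('GC', 'CG', 'U', 'G'): 0.5,
    ('GC', 'CG', 'U', 'U'): -0.1,
    ('GC', 'GC', 'A', 'A'): 0.8,
    ('GC', 'GC', 'A', 'C'): 0.5,
    ('GC', 'GC', 'A', 'G'): 0.5,
    ('GC', 'GC', 'A', 'U'): 0.5,
    ('GC', 'GC', 'C', 'A'): 0.5,
    ('GC', 'GC', 'C', 'C'): 0.5,
    ('GC', 'GC', 'C', 'G'): 0.5,
    ('GC', 'GC', 'C', 'U'): 0.5,
    ('GC', 'GC', 'G', 'A'): 0.5,
    ('GC', 'GC', 'G', 'C'): 0.5,
    ('GC', 'GC', 'G', 'G'): -2.3,
    ('GC', 'GC', 'G', 'U'): 0.5,
    ('GC', 'GC', 'U', 'A'): 0.5,
    ('GC', 'GC', 'U', 'C'): 0.5,
    ('GC', 'GC', 'U', 'G'): 0.5,
    ('GC', 'GC', 'U', 'U'): -0.6,
    ('GC', 'GU', 'A', 'A'): 1.9,
    ('GC', 'GU', 'A', 'C'): 1.2,
    ('GC', 'GU', 'A', 'G'): 1.5,
    ('GC', 'GU', 'A', 'U'): 1.2,
    ('GC', 'GU', 'C', 'A'): 1.2,
    ('GC', 'GU', 'C', 'C'): 1.2,
    ('GC', 'GU', 'C', 'G'): 1.2,
    ('GC', 'GU', 'C', 'U'): 1.2,
    ('GC', 'GU', 'G', 'A'): 1.2,
    ('GC', 'GU', 'G', 'C'): 1.2,
    ('GC', 'GU', 'G', 'G'): -1.4,
    ('GC', 'GU', 'G', 'U'): 1.2,
    ('GC', 'GU', 'U', 'A'): 1.2,
    ('GC', 'GU', 'U', 'C'): 1.2,
    ('GC', 'GU', 'U', 'G'): 1.2,
    ('GC', 'GU', 'U', 'U'): 1.5,
    ('GC', 'UA', 'A', 'A'): 1.2,
    ('GC', 'UA', 'A', 'C'): 1.2,
    ('GC', 'UA', 'A', 'G'): 1.2,
    ('GC', 'UA', 'A', 'U'): 1.2,
    ('GC', 'UA', 'C', 'A'): 1.2,
    ('GC', 'UA', 'C', 'C'): 1.2,
    ('GC', 'UA', 'C', 'G'): 1.2,
    ('GC', 'UA', 'C', 'U'): 1.2,
    ('GC', 'UA', 'G', 'A'): 1.2,
    ('GC', 'UA', 'G', 'C'): 1.2,
    ('GC', 'UA', 'G', 'G'): -1.4,
    ('GC', 'UA', 'G', 'U'): 1.2,
    ('GC', 'UA', 'U', 'A'): 1.2,
    ('GC', 'UA', 'U', 'C'): 1.2,
    ('GC', 'UA', 'U', 'G'): 1.2,
    ('GC', 'UA', 'U', 'U'): 1.2,
    ('GC', 'UG', 'A', 'A'): 1.6,
    ('GC', 'UG', 'A', 'C'): 1.2,
    ('GC', 'UG', 'A', 'G'): 1.0,
    ('GC', 'UG', 'A', 'U'): 1.2,
    ('GC', 'UG', 'C', 'A'): 1.2,
    ('GC', 'UG', 'C', 'C'): 1.2,
    ('GC', 'UG', 'C', 'G'): 1.2,
    ('GC', 'UG', 'C', 'U'): 1.2,
    ('GC', 'UG', 'G', 'A'): 1.2,
    ('GC', 'UG', 'G', 'C'): 1.2,
    ('GC', 'UG', 'G', 'G'): -1.4,
    ('GC', 'UG', 'G', 'U'): 1.2,
    ('GC', 'UG', 'U', 'A'): 1.2,
    ('GC', 'UG', 'U', 'C'): 1.2,
    ('GC', 'UG', 'U', 'G'): 1.2,
    ('GC', 'UG', 'U', 'U'): 0.7,
    ('GU', 'AU', 'A', 'A'): 1.9,
    ('GU', 'AU', 'A', 'C'): 1.9,
    ('GU', 'AU', 'A', 'G'): 1.9,
    ('GU', 'AU', 'A', 'U'): 1.9,
    ('GU', 'AU', 'C', 'A'): 1.9,
    ('GU', 'AU', 'C', 'C'): 1.9,
    ('GU', 'AU', 'C', 'G'): 1.9,
    ('GU', 'AU', 'C', 'U'): 1.9,
    ('GU', 'AU', 'G', 'A'): 1.9,
    ('GU', 'AU', 'G', 'C'): 1.9,
    ('GU', 'AU', 'G', 'G'): -0.7,
    ('GU', 'AU', 'G', 'U'): 1.9,
    ('GU', 'AU', 'U', 'A'): 1.9,
    ('GU', 'AU', 'U', 'C'): 1.9,
    ('GU', 'AU', 'U', 'G'): 1.9,
    ('GU', 'AU', 'U', 'U'): 1.2,
    ('GU', 'CG', 'A', 'A'): 0.6,
    ('GU', 'CG', 'A', 'C'): 1.2,
    ('GU', 'CG', 'A', 'G'): -0.2,
    ('GU', 'CG', 'A', 'U'): 1.2,
    ('GU', 'CG', 'C', 'A'): 0.5,
    ('GU', 'CG', 'C', 'C'): 1.2,
    ('GU', 'CG', 'C', 'G'): 1.2,
    ('GU', 'CG', 'C', 'U'): 1.0,
    ('GU', 'CG', 'G', 'A'): 1.2,
    ('GU', 'CG', 'G', 'C'): 1.2,
    ('GU', 'CG', 'G', 'G'): -1.4,
    ('GU', 'CG', 'G', 'U'): 1.2,
    ('GU', 'CG', 'U', 'A'): 1.2,
    ('GU', 'CG', 'U', 'C'): 1.2,
    ('GU', 'CG', 'U', 'G'): 1.2,
    ('GU', 'CG', 'U', 'U'): 1.1,
    ('GU', 'GC', 'A', 'A'): 1.9,
    ('GU', 'GC', 'A', 'C'): 1.2,
    ('GU', 'GC', 'A', 'G'): 1.2,
    ('GU', 'GC', 'A', 'U'): 1.2,
    ('GU', 'GC', 'C', 'A'): 1.2,
    ('GU', 'GC', 'C', 'C'): 1.2,
    ('GU', 'GC', 'C', 'G'): 1.2,
    ('GU', 'GC', 'C', 'U'): 1.2,
    ('GU', 'GC', 'G', 'A'): 1.5,
    ('GU', 'GC', 'G', 'C'): 1.2,
    ('GU', 'GC', 'G', 'G'): -1.4,
    ('GU', 'GC', 'G', 'U'): 1.2,
    ('GU', 'GC', 'U', 'A'): 1.2,
    ('GU', 'GC', 'U', 'C'): 1.2,
    ('GU', 'GC', 'U', 'G'): 1.2,
    ('GU', 'GC', 'U', 'U'): 1.5,
    ('GU', 'GU', 'A', 'A'): 1.9,
    ('GU', 'GU', 'A', 'C'): 1.9,
    ('GU', 'GU', 'A', 'G'): 1.9,
    ('GU', 'GU', 'A', 'U'): 1.9,
    ('GU', 'GU', 'C', 'A'): 1.9,
    ('GU', 'GU', 'C', 'C'): 1.9,
    ('GU', 'GU', 'C', 'G'): 1.9,
    ('GU', 'GU', 'C', 'U'): 1.9,
    ('GU', 'GU', 'G', 'A'): 1.9,
    ('GU', 'GU', 'G', 'C'): 1.9,
    ('GU', 'GU', 'G', 'G'): -0.7,
    ('GU', 'GU', 'G', 'U'): 1.9,
    ('GU', 'GU', 'U', 'A'): 1.9,
    ('GU', 'GU', 'U', 'C'): 1.9,
    ('GU', 'GU', 'U', 'G'): 1.9,
    ('GU', 'GU', 'U', 'U'): 1.2,
    ('GU', 'UA', 'A', 'A'): 1.9,
    ('GU', 'UA', 'A', 'C'): 1.9,
    ('GU', 'UA', 'A', 'G'): 1.9,
    ('GU', 'UA', 'A', 'U'): 1.9,
    ('GU', 'UA', 'C', 'A'): 1.9,
    ('GU', 'UA', 'C', 'C'): 1.9,
    ('GU', 'UA', 'C', 'G'): 1.9,
    ('GU', 'UA', 'C', 'U'): 1.9,
    ('GU', 'UA', 'G', 'A'): 1.9,
    ('GU', 'UA', 'G', 'C'): 1.9,
    ('GU', 'UA', 'G', 'G'): -0.7,
    ('GU', 'UA', 'G', 'U'): 1.9,
    ('GU', 'UA', 'U', 'A'): 1.9,
    ('GU', 'UA', 'U', 'C'): 1.9,
    ('GU', 'UA', 'U', 'G'): 1.9,
    ('GU', 'UA', 'U', 'U'): 1.6,
    ('GU', 'UG', 'A', 'A'): 1.9,
    ('GU', 'UG', 'A', 'C'): 1.9,
    ('GU', 'UG', 'A', 'G'): 1.9,
    ('GU', 'UG', 'A', 'U'): 1.9,
    ('GU', 'UG', 'C', 'A'): 1.9,
    ('GU', 'UG', 'C', 'C'): 1.9,
    ('GU', 'UG', 'C', 'G'): 1.9,
    ('GU', 'UG', 'C', 'U'): 1.9,
    ('GU', 'UG', 'G', 'A'): 1.9,
    ('GU', 'UG', 'G', 'C'): 1.9,
    ('GU', 'UG', 'G', 'G'): -0.7,
    ('GU', 'UG', 'G', 'U'): 1.9,
    ('GU', 'UG', 'U', 'A'): 1.9,
    ('GU', 'UG', 'U', 'C'): 1.9,
    ('GU', 'UG', 'U', 'G'): 1.9,
    ('GU', 'UG', 'U', 'U'): 1.6,
    ('UA', 'AU', 'A', 'A'): 1.9,
    ('UA', 'AU', 'A', 'C'): 1.9,
    ('UA', 'AU', 'A', 'G'): 1.9,
    ('UA', 'AU', 'A', 'U'): 1.9,
    ('UA', 'AU', 'C', 'A'): 1.9,
    ('UA', 'AU', 'C', 'C'): 1.9,
    ('UA', 'AU', 'C', 'G'): 1.9,
    ('UA', 'AU', 'C', 'U'): 1.9,
    ('UA', 'AU', 'G', 'A'): 1.9,
    ('UA', 'AU', 'G', 'C'): 1.9,
    ('UA', 'AU', 'G', 'G'): -0.7,
    ('UA', 'AU', 'G', 'U'): 1.9,
    ('UA', 'AU', 'U', 'A'): 1.9,
    ('UA', 'AU', 'U', 'C'): 1.9,
    ('UA', 'AU', 'U', 'G'): 1.9,
    ('UA', 'AU', 'U', 'U'): 1.5,
    ('UA', 'CG', 'A', 'A'): 1.2,
    ('UA', 'CG', 'A', 'C'): 1.2,
    ('UA', 'CG', 'A', 'G'): 1.2,
    ('UA', 'CG', 'A', 'U'): 1.2,
    ('UA', 'CG', 'C', 'A'): 1.2,
    ('UA', 'CG', 'C', 'C'): 1.2,
    ('UA', 'CG', 'C', 'G'): 1.2,
    ('UA', 'CG', 'C', 'U'): 1.2,
    ('UA', 'CG', 'G', 'A'): 1.2,
    ('UA', 'CG', 'G', 'C'): 1.2,
    ('UA', 'CG', 'G', 'G'): -1.4,
    ('UA', 'CG', 'G', 'U'): 1.2,
    ('UA', 'CG', 'U', 'A'): 1.2,
    ('UA', 'CG', 'U', 'C'): 1.2,
    ('UA', 'CG', 'U', 'G'): 1.2,
    ('UA', 'CG', 'U', 'U'): 1.2,
    ('UA', 'GC', 'A', 'A'): 1.2,
    ('UA', 'GC', 'A', 'C'): 1.2,
    ('UA', 'GC', 'A', 'G'): 1.2,
    ('UA', 'GC', 'A', 'U'): 1.2,
    ('UA', 'GC', 'C', 'A'): 1.2,
    ('UA', 'GC', 'C', 'C'): 1.2,
    ('UA', 'GC', 'C', 'G'): 1.2,
    ('UA', 'GC', 'C', 'U'): 1.2,
    ('UA', 'GC', 'G', 'A'): 1.2,
    ('UA', 'GC', 'G', 'C'): 1.2,
    ('UA', 'GC', 'G', 'G'): -1.4,
    ('UA', 'GC', 'G', 'U'): 1.2,
    ('UA', 'GC', 'U', 'A'): 1.2,
    ('UA', 'GC', 'U', 'C'): 1.2,
    ('UA', 'GC', 'U', 'G'): 1.2,
    ('UA', 'GC', 'U', 'U'): 1.2,
    ('UA', 'GU', 'A', 'A'): 1.9,
    ('UA', 'GU', 'A', 'C'): 1.9,
    ('UA', 'GU', 'A', 'G'): 1.9,
    ('UA', 'GU', 'A', 'U'): 1.9,
    ('UA', 'GU', 'C', 'A'): 1.9,
    ('UA', 'GU', 'C', 'C'): 1.9,
    ('UA', 'GU', 'C', 'G'): 1.9,
    ('UA', 'GU', 'C', 'U'): 1.9,
    ('UA', 'GU', 'G', 'A'): 1.9,
    ('UA', 'GU', 'G', 'C'): 1.9,
    ('UA', 'GU', 'G', 'G'): -0.7,
    ('UA', 'GU', 'G', 'U'): 1.9,
    ('UA', 'GU', 'U', 'A'): 1.9,
    ('UA', 'GU', 'U', 'C'): 1.9,
    ('UA', 'GU', 'U', 'G'): 1.9,
    ('UA', 'GU', 'U', 'U'): 1.6,
    ('UA', 'UA', 'A', 'A'): 1.9,
    ('UA', 'UA', 'A', 'C'): 1.9,
    ('UA', 'UA', 'A', 'G'): 1.9,
    ('UA', 'UA', 'A', 'U'): 1.9,
    ('UA', 'UA', 'C', 'A'): 1.9,
    ('UA', 'UA', 'C', 'C'): 1.9,
    ('UA', 'UA', 'C', 'G'): 1.9,
    ('UA', 'UA', 'C', 'U'): 1.9,
    ('UA', 'UA', 'G', 'A'): 1.9,
    ('UA', 'UA', 'G', 'C'): 1.9,
    ('UA', 'UA', 'G', 'G'): -0.7,
    ('UA', 'UA', 'G', 'U'): 1.9,
    ('UA', 'UA', 'U', 'A'): 1.9,
    ('UA', 'UA', 'U', 'C'): 1.9,
    ('UA', 'UA', 'U', 'G'): 1.9,
    ('UA', 'UA', 'U', 'U'): 1.7,
    ('UA', 'UG', 'A', 'A'): 1.9,
    ('UA', 'UG', 'A', 'C'): 1.9,
    ('UA', 'UG', 'A', 'G'): 1.9,
    ('UA', 'UG', 'A', 'U'): 1.9,
    ('UA', 'UG', 'C', 'A'): 1.9,
    ('UA', 'UG', 'C', 'C'): 1.9,
    ('UA', 'UG', 'C', 'G'): 1.9,
    ('UA', 'UG', 'C', 'U'): 1.9,
    ('UA', 'UG', 'G', 'A'): 1.9,
    ('UA', 'UG', 'G', 'C'): 1.9,
    ('UA', 'UG', 'G', 'G'): -0.7,
    ('UA', 'UG', 'G', 'U'): 1.9,
    ('UA', 'UG', 'U', 'A'): 1.9,
    ('UA', 'UG', 'U', 'C'): 1.9,
    ('UA', 'UG', 'U', 'G'): 1.9,
    ('UA', 'UG', 'U', 'U'): 1.9,
    ('UG', 'AU', 'A', 'A'): 1.9,
    ('UG', 'AU', 'A', 'C'): 1.9,
    ('UG', 'AU', 'A', 'G'): 1.9,
    ('UG', 'AU', 'A', 'U'): 1.9,
    ('UG', 'AU', 'C', 'A'): 1.9,
    ('UG', 'AU', 'C', 'C'): 1.9,
    ('UG', 'AU', 'C', 'G'): 1.9,
    ('UG', 'AU', 'C', 'U'): 1.9,
    ('UG', 'AU', 'G', 'A'): 1.9,
    ('UG', 'AU', 'G', 'C'): 1.9,
    ('UG', 'AU', 'G', 'G'): -0.7,
    ('UG', 'AU', 'G', 'U'): 1.9,
    ('UG', 'AU', 'U', 'A'): 1.9,
    ('UG', 'AU', 'U', 'C'): 1.9,
    ('UG', 'AU', 'U', 'G'): 1.9,
    ('UG', 'AU', 'U', 'U'): 1.6,
    ('UG', 'CG', 'A', 'A'): 2.2,
    ('UG', 'CG', 'A', 'C'): 1.2,
    ('UG', 'CG', 'A', 'G'): 1.2,
    ('UG', 'CG', 'A', 'U'): 1.2,
    ('UG', 'CG', 'C', 'A'): 1.3,
    ('UG', 'CG', 'C', 'C'): 1.7,
    ('UG', 'CG', 'C', 'G'): 1.2,
    ('UG', 'CG', 'C', 'U'): 1.2,
    ('UG', 'CG', 'G', 'A'): 1.2,
    ('UG', 'CG', 'G', 'C'): 1.2,
    ('UG', 'CG', 'G', 'G'): -1.4,
    ('UG', 'CG', 'G', 'U'): 1.2,
    ('UG', 'CG', 'U', 'A'): 1.2,
    ('UG', 'CG', 'U', 'C'): 1.2,
    ('UG', 'CG', 'U', 'G'): 1.2,
    ('UG', 'CG', 'U', 'U'): 1.1,
    ('UG', 'GC', 'A', 'A'): 1.6,
    ('UG', 'GC', 'A', 'C'): 1.2,
    ('UG', 'GC', 'A', 'G'): 1.2,
    ('UG', 'GC', 'A', 'U'): 1.2,
    ('UG', 'GC', 'C', 'A'): 1.2,
    ('UG', 'GC', 'C', 'C'): 1.2,
    ('UG', 'GC', 'C', 'G'): 1.2,
    ('UG', 'GC', 'C', 'U'): 1.2,
    ('UG', 'GC', 'G', 'A'): 1.0,
    ('UG', 'GC', 'G', 'C'): 1.2,
    ('UG', 'GC', 'G', 'G'): -1.4,
    ('UG', 'GC', 'G', 'U'): 1.2,
    ('UG', 'GC', 'U', 'A'): 1.2,
    ('UG', 'GC', 'U', 'C'): 1.2,
    ('UG', 'GC', 'U', 'G'): 1.2,
    ('UG', 'GC', 'U', 'U'): 0.7,
    ('UG', 'GU', 'A', 'A'): 1.9,
    ('UG', 'GU', 'A', 'C'): 1.9,
    ('UG', 'GU', 'A', 'G'): 1.9,
    ('UG', 'GU', 'A', 'U'): 1.9,
    ('UG', 'GU', 'C', 'A'): 1.9,
    ('UG', 'GU', 'C', 'C'): 1.9,
    ('UG', 'GU', 'C', 'G'): 1.9,
    ('UG', 'GU', 'C', 'U'): 1.9,
    ('UG', 'GU', 'G', 'A'): 1.9,
    ('UG', 'GU', 'G', 'C'): 1.9,
    ('UG', 'GU', 'G', 'G'): -0.7,
    ('UG', 'GU', 'G', 'U'): 1.9,
    ('UG', 'GU', 'U', 'A'): 1.9,
    ('UG', 'GU', 'U', 'C'): 1.9,
    ('UG', 'GU', 'U', 'G'): 1.9,
    ('UG', 'GU', 'U', 'U'): 1.6,
    ('UG', 'UA', 'A', 'A'): 1.9,
    ('UG', 'UA', 'A', 'C'): 1.9,
    ('UG', 'UA', 'A', 'G'): 1.9,
    ('UG', 'UA', 'A', 'U'): 1.9,
    ('UG', 'UA', 'C', 'A'): 1.9,
    ('UG', 'UA', 'C', 'C'): 1.9,
    ('UG', 'UA', 'C', 'G'): 1.9,
    ('UG', 'UA', 'C', 'U'): 1.9,
    ('UG', 'UA', 'G', 'A'): 1.9,
    ('UG', 'UA', 'G', 'C'): 1.9,
    ('UG', 'UA', 'G', 'G'): -0.7,
    ('UG', 'UA', 'G', 'U'): 1.9,
    ('UG', 'UA', 'U', 'A'): 1.9,
    ('UG', 'UA', 'U', 'C'): 1.9,
    ('UG', 'UA', 'U', 'G'): 1.9,
    ('UG', 'UA', 'U', 'U'): 1.9,
    ('UG', 'UG', 'A', 'A'): 1.9,
    ('UG', 'UG', 'A', 'C'): 1.9,
    ('UG', 'UG', 'A', 'G'): 1.9,
    ('UG', 'UG', 'A', 'U'): 1.9,
    ('UG', 'UG', 'C', 'A'): 1.9,
    ('UG', 'UG', 'C', 'C'): 1.9,
    ('UG', 'UG', 'C', 'G'): 1.9,
    ('UG', 'UG', 'C', 'U'): 1.9,
    ('UG', 'UG', 'G', 'A'): 1.9,
    ('UG', 'UG', 'G', 'C'): 1.9,
    ('UG', 'UG', 'G', 'G'): -0.7,
    ('UG', 'UG', 'G', 'U'): 1.9,
    ('UG', 'UG', 'U', 'A'): 1.9,
    ('UG', 'UG', 'U', 'C'): 1.9,
    ('UG', 'UG', 'U', 'G'): 1.9,
    ('UG', 'UG', 'U', 'U'): 1.9,
}
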