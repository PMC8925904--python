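{
    "onset": {
        "Description": "Time in seconds of the event marker relative to the start of the recording."
    },
    "duration": {
        "Description": "Duration of the event in seconds; 'n/a' when not recorded."
    },
    "sample": {
        "Description": "Data sample index corresponding to the event onset."
    },
    "value": {
        "Description": "Trigger value emitted by the experiment control program; retained for reference."
    },
    "trial": {
        "Description": "Number of the trial this event marker belongs to."
    },
    "event_type": {
        "Description": "The type of event marker.",
        "Levels": {
            "setup_left_sym": "Setup meta-event: a left index-finger press indicates a symmetric judgment.",
            "setup_right_sym": "Setup meta-event: a right index-finger press indicates a symmetric judgment.",
            "show_cross": "Display of the white fixation cross.",
            "show_face_initial": "Display of the first face image of the run, with no recorded preceding cross.",
            "show_face": "Display of a face image, ending the cross-only period.",
            "show_circle": "Display of the white circle, ending the face display.",
            "left_press": "Key press with the left index finger.",
            "right_press": "Key press with the right index finger."
        },
        "HED": {
            "setup_left_sym": "Experiment-control, (Def/Left-sym-cond, Onset)",
            "setup_right_sym": "Experiment-control, (Def/Right-sym-cond, Onset)",
            "show_cross": "Sensory-event, (Def/Cross-only, Onset), (Def/Fixation-task, Onset), (Def/Circle-only, Offset)",
            "show_face_initial": "Sensory-event, (Def/Face-image, Onset), (Def/Blink-inhibition, Onset), (Def/Fixation-task, Onset)",
            "show_face": "Sensory-event, (Def/Face-image, Onset), (Def/Blink-inhibition, Onset), (Def/Cross-only, Offset)",
            "show_circle": "Sensory-event, (Def/Circle-only, Onset), (Def/Face-image, Offset), (Def/Blink-inhibition, Offset), (Def/Fixation-task, Offset)",
            "left_press": "Agent-action, Def/Press-left-finger",
            "right_press": "Agent-action, Def/Press-right-finger"
        }
    },
    "face_type": {
        "Description": "Category of the displayed face image.",
        "Levels": {
            "famous_face": "A face that should be recognized by the participants.",
            "unfamiliar_face": "A face that should not be recognized by the participants.",
            "scrambled_face": "A scrambled face image generated by taking the 2D FFT of a face."
        },
        "HED": {
            "famous_face": "Def/Famous-face-cond",
            "unfamiliar_face": "Def/Unfamiliar-face-cond",
            "scrambled_face": "Def/Scrambled-face-cond"
        }
    },
    "rep_status": {
        "Description": "Repetition status of the displayed face image.",
        "Levels": {
            "first_show": "The first display of this face.",
            "immediate_repeat": "This face was the same as the immediately preceding one.",
            "delayed_repeat": "This face was first seen 5 to 15 face presentations ago."
        },
        "HED": {
            "first_show": "Def/First-show-cond",
            "immediate_repeat": "Def/Immediate-repeat-cond",
            "delayed_repeat": "Def/Delayed-repeat-cond"
        }
    },
    "rep_lag": {
        "Description": "Number of face presentations since this face was first presented; 'n/a' on a first showing.",
        "HED": "(Item-interval/#)"
    },
    "stim_file": {
        "Description": "Name of the presented stimulus image file.",
        "HED": "(Image, Pathname/#)"
    },
    "hed_defs_sensory": {
        "Description": "Named concepts for the recurring sensory presentations.",
        "HED": "(Definition/Face-image, ((Image, Face), (Cross, White), Visual-presentation)), (Definition/Cross-only, ((Cross, White), Visual-presentation)), (Definition/Circle-only, ((Circle, White), Visual-presentation))"
    },
    "hed_defs_actions": {
        "Description": "Named concepts for the participant key-press actions.",
        "HED": "(Definition/Press-left-finger, ((Index-finger, Left-hand), (Press, Keyboard-key))), (Definition/Press-right-finger, ((Index-finger, Right-hand), (Press, Keyboard-key)))"
    },
    "hed_defs_tasks": {
        "Description": "Named concepts for the instructed eye-control tasks.",
        "HED": "(Definition/Fixation-task, (Explicit-task, Fixate, (Cross, White))), (Definition/Blink-inhibition, (Explicit-task, Inhibit-blinks))"
    },
    "hed_defs_conditions": {
        "Description": "Named concepts encoding the experimental design factors and their levels.",
        "HED": "(Definition/Famous-face-cond, (Condition-variable/Face-type, (Image, (Face, Famous)))), (Definition/Unfamiliar-face-cond, (Condition-variable/Face-type, (Image, (Face, Unfamiliar)))), (Definition/Scrambled-face-cond, (Condition-variable/Face-type, (Image, (Face, Disordered)))), (Definition/First-show-cond, (Condition-variable/Repetition-status, Item-count/1)), (Definition/Immediate-repeat-cond, (Condition-variable/Repetition-status, Item-count/2, Item-interval/1)), (Definition/Delayed-repeat-cond, (Condition-variable/Repetition-status, Item-count/2)), (Definition/Left-sym-cond, (Condition-variable/Key-assignment, ((Index-finger, Left-hand), (Press, Keyboard-key)))), (Definition/Right-sym-cond, (Condition-variable/Key-assignment, ((Index-finger, Right-hand), (Press, Keyboard-key))))"
    }
}
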