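Event : Something that happens at a point or over an interval of the recording.
  Sensory-event : Something perceivable by the participant occurs.
  Agent-action : An action engaged in by an agent.
  Experiment-control : An event pertaining to the control flow of the experiment.
  Experiment-procedure : An administrative or procedural step of the experiment.
  Data-feature : An event derived post hoc from the recorded data itself.
Agent : An entity that can act on its own initiative.
  Experiment-participant : A person who participates in the experiment.
  Experimenter : A person conducting the experiment.
Action : Something an agent does.
  Press : Apply pressure to something.
  Release : Stop applying pressure to something.
  Fixate : Hold gaze steadily on a target.
  Inhibit-blinks : Suppress eye blinks.
  Move : Change position or posture.
Item : An independently existing thing.
  Biological-item : An item of biological origin.
    Body-part : A part of an organism's body.
      Head : The upper part of the body.
        Face : The front of the head.
      Hand : The grasping body part at the end of the arm.
        Left-hand : The hand on the left side of the body.
        Right-hand : The hand on the right side of the body.
        Index-finger : The finger next to the thumb.
  Object : A thing perceptible by the senses.
    Geometric-object : An object defined primarily by its geometry.
      2D-shape : A two-dimensional geometric shape.
        Ellipse : A regular oval shape.
          Circle : An ellipse whose axes are equal.
        Cross : A figure formed by two short intersecting lines.
        Rectangle : A parallelogram with four right angles.
      3D-shape : A three-dimensional geometric shape.
    Man-made-object : An object made by human beings.
      Media : Items used to store or communicate information.
        Image : A two-dimensional visual representation.
        Movie : A sequence of moving images.
      Device : An object made for a particular purpose.
        Keyboard-key : A key on a keyboard device.
        Computer-screen : An electronic display surface.
Property : An attribute of or qualifier for something else.
  Sensory-property : A property relating to sensation.
    Sensory-presentation : The manner in which something is presented to the senses.
      Visual-presentation : Presented so it can be seen.
      Auditory-presentation : Presented so it can be heard.
    Color : The hue of something.
      White
      Black
      Gray
      Red
      Green
      Blue
  Characteristic-property : An inherent characteristic of an item.
    Famous : Widely known to the general public.
    Unfamiliar : Not known to the observer.
    Disordered : Lacking systematic arrangement.
  Agent-property : A property of an agent.
    Sex : The biological sex of an agent or depicted being.
      Female
      Male
  Informational-property : A property conveying information about something.
    Pathname : The name of a file system path.
      #
    Description : A free-text description.
      #
  Data-property : A quantitative property attached to data.
    Item-count : The ordinal count of occurrences of an item.
      #
    Item-interval : The number of intervening occurrences since the last occurrence.
      #
  Temporal-property : A property pertaining to time.
    Onset : Marks the start of an event process unfolding over time.
    Offset : Marks the end of an event process unfolding over time.
    Duration : The length in time of an event process.
      #
  Organizational-property : A property used to organize annotations.
    Definition : Declares a named, reusable annotation concept.
      #
    Def : References a declared definition by name.
      #
    Def-expand : Marks the in-place expansion of a referenced definition.
      #
    Condition-variable : Marks a factor of the experimental design; the value is the factor name.
      #
    Event-context : Groups information about event processes ongoing at this event's time.
    Experimental-trial : Marks membership in an experimental trial.
    Time-block : Marks membership in a temporal block of the recording.
Task : An organized activity the participant performs.
  Explicit-task : A task the participant was instructed to perform.
  Implicit-task : A task the participant may perform without explicit instruction.
Relation : A relationship between two entities.
  Spatial-relation : A relationship in space.
    Center-of : Positioned at the center of something.
    Left-of : Positioned to the left of something.
    Right-of : Positioned to the right of something.
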