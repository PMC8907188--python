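What is this guy doing?
Someone needs to do something about this!
This guy has lost it!
Tell him to calm down...
This guy is ridiculous!
Tell him to shut up!
Come on, who is going to tell him to stop?!
Someone needs to do something about this!
Who is going to tell him to stop?!
This guy has lost it...
Tell him to shut up!
This guy is ridiculous!
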