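{
  "greet": "Hi! I can help you find a step or action that fits how you're doing today.",
  "ask_mood": "How are you feeling right now?",
  "ask_topic": "What would you like some help or ideas with?",
  "reprompt_mood": "No rush - even a word or two about how you feel helps.",
  "reprompt_topic": "Anything at all you'd like to work on? A word or two is fine.",
  "skip": "That's okay, we can skip that.",
  "confirm": "Thanks! Shall I look for some suggestions for you?",
  "done": "Here is what I found. A moderator will also see a short profile of our chat."
}
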