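{
  "taxonomy": {
    "parents": ["Coping", "Connecting", "Enhancing"],
    "children": {
      "Coping": ["Solving Problems", "Kicking the Habit", "Beating Sadness and Worries"],
      "Connecting": ["Overcoming Conflict", "Boosting Relationships", "Stories Like Yours"],
      "Enhancing": ["Making Happiness", "Wellbeing with Mindfulness", "Work and Study"]
    }
  },
  "strengths": [
    "Courage", "Discretion", "Creativity", "Curiosity",
    "Kindness", "Gratitude", "Hope", "Humor", "Honesty", "Perseverance",
    "Teamwork", "Fairness", "Leadership", "Forgiveness", "Humility",
    "Zest", "Love of Learning", "Perspective", "Social Intelligence",
    "Self-Regulation", "Appreciation of Beauty", "Spirituality",
    "Enthusiasm", "Patience"
  ],
  "items": [
    {
      "id": "step-work-study",
      "kind": "step",
      "title": "Thriving at Work and Study",
      "valence": "either",
      "emotion_relevance": {"anger": 0.2, "disgust": 0.0, "fear": 0.7, "joy": 0.1, "sadness": 0.3},
      "keywords": ["work", "job", "stress", "stressed", "study", "pressure"],
      "subtags": ["Work and Study"],
      "strengths": [],
      "related_ids": ["step-mindfulness"]
    },
    {
      "id": "step-mindfulness",
      "kind": "step",
      "title": "Wellbeing with Mindfulness",
      "valence": "either",
      "emotion_relevance": {"anger": 0.3, "disgust": 0.1, "fear": 0.5, "joy": 0.2, "sadness": 0.4},
      "keywords": ["mindfulness", "calm", "breathing", "relax"],
      "subtags": ["Wellbeing with Mindfulness"],
      "strengths": [],
      "related_ids": []
    },
    {
      "id": "step-relationships",
      "kind": "step",
      "title": "Boosting Relationships",
      "valence": "positive",
      "emotion_relevance": {"anger": 0.1, "disgust": 0.0, "fear": 0.1, "joy": 0.8, "sadness": 0.1},
      "keywords": ["friend", "family", "talk", "connection"],
      "subtags": ["Boosting Relationships"],
      "strengths": [],
      "related_ids": []
    },
    {
      "id": "step-sadness",
      "kind": "step",
      "title": "Beating Sadness and Worries",
      "valence": "negative",
      "emotion_relevance": {"anger": 0.1, "disgust": 0.0, "fear": 0.5, "joy": 0.0, "sadness": 0.9},
      "keywords": ["sadness", "worry", "mood", "low"],
      "subtags": ["Beating Sadness and Worries"],
      "strengths": [],
      "related_ids": ["step-mindfulness"]
    },
    {
      "id": "action-breathing-break",
      "kind": "action",
      "title": "Take a Breathing Break at Work",
      "valence": "either",
      "emotion_relevance": {"anger": 0.2, "disgust": 0.0, "fear": 0.6, "joy": 0.1, "sadness": 0.2},
      "keywords": ["work", "job", "stress", "breathing", "break"],
      "subtags": ["Work and Study", "Wellbeing with Mindfulness"],
      "strengths": ["Self-Regulation", "Perseverance"],
      "related_ids": []
    },
    {
      "id": "action-gratitude-note",
      "kind": "action",
      "title": "Write a Gratitude Note",
      "valence": "positive",
      "emotion_relevance": {"anger": 0.0, "disgust": 0.0, "fear": 0.1, "joy": 0.9, "sadness": 0.1},
      "keywords": ["gratitude", "thanks", "happiness", "note"],
      "subtags": ["Making Happiness"],
      "strengths": ["Gratitude", "Kindness"],
      "related_ids": []
    },
    {
      "id": "action-reach-out",
      "kind": "action",
      "title": "Reach Out to a Friend",
      "valence": "either",
      "emotion_relevance": {"anger": 0.1, "disgust": 0.0, "fear": 0.3, "joy": 0.4, "sadness": 0.6},
      "keywords": ["friend", "talk", "support", "call"],
      "subtags": ["Boosting Relationships"],
      "strengths": ["Courage", "Kindness"],
      "related_ids": []
    }
  ]
}
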