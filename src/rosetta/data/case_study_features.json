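{
 "format": "rosetta-features/1",
 "features": [
  {
   "id": "Cognoa_Cognitive_Behavioral_Emotional_AngerControl_CalmingDown",
   "subject": "Child is difficult to calm when upset"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Emotional_AnxietyInternalization_Worry",
   "subject": "Child tends to be worrisome"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Sensory_Intrigued",
   "subject": "Child has an unusual interest in certain sensory stimuli"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Atypicality_OddBehavior",
   "subject": "Others seem to think the child acts strangely"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Atypicality_OddInteractions",
   "subject": "Child has awkward interactions with others"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Atypicality_OutOfStepWithOthers",
   "subject": "Child does not care about relating to others"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Awareness_GetsTakenAdvantageOf",
   "subject": "Child has difficulty recognizing manipulative behavior"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Awareness_SenseOfHumor",
   "subject": "Child understands humor"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Awareness_Unfair",
   "subject": "Child has difficulty understanding fairness"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_GroupPlay",
   "subject": "Child participates in group play"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_SharedInterests_Objects",
   "subject": "Child likes to direct others' attention to objects of interest"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_SharedInterests_SharingToys",
   "subject": "Child offers to share toys"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Staring_BlankStares",
   "subject": "Child tends to stare blankly"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Withdrawal_Avoidance",
   "subject": "Child has little interest in others"
  },
  {
   "id": "Cognoa_Cognitive_Behavioral_Social_Imitation",
   "subject": "Child imitates others' behavior"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Attention_CarelessMistakes",
   "subject": "Child tends to make careless mistakes"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Attention_FollowingDirections",
   "subject": "Child has difficulty following directions"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Attention_LosesThings",
   "subject": "Child frequently loses belongings"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Imagination_WithToys",
   "subject": "Child uses creativity in play"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Impulsivity_OutOfControl",
   "subject": "Child tends to act wild or out of control"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Impulsivity_Verbal",
   "subject": "Child tends to blurt out the first thing that comes to mind"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Memory_CompleteActivities",
   "subject": "Child tends to be forgetful in everyday tasks"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Memory_ShortTerm",
   "subject": "Child has problems with short term memory"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_Reasoning_LacksFollowThrough",
   "subject": "Child tends to lack follow-through"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_CleaningUpAfterSelf",
   "subject": "Child has a tendency to leave behind messes"
  },
  {
   "id": "Cognoa_Cognitive_ExecutiveFunctioning_SloppyWork",
   "subject": "Child has sloppy written work"
  },
  {
   "id": "Cognoa_Cognitive_LanguageCommunication_Expressive_SocialChatting",
   "subject": "Child is comfortable with social chatting"
  },
  {
   "id": "Cognoa_Cognitive_LanguageCommunication_Speech_UnusualOrOdd",
   "subject": "Child has unusual tone or rhythm in speech"
  },
  {
   "id": "Cognoa_Cognitive_LanguageCommunication_Receptive_Conversations",
   "subject": "Child can respond to back-and-forth conversations"
  },
  {
   "id": "Cognoa_Motor_Fine_Grip",
   "subject": "Child has the ability to grip objects"
  }
 ]
}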