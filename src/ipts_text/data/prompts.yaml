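# Prompt settings for the three automated-responder contexts. These are
# configuration for a pluggable responder contract; no external model is
# called by this package (the shipped template responder stands in).
AI-1:
  description: post only
  prompt: |
    You are replying in an online peer-support community. Write a supportive
    response to the following post.

    Post: {post}
AI-2:
  description: post + IPTS category
  prompt: |
    You are replying in an online peer-support community. The post below has
    been categorized under the Interpersonal Theory of Suicide as: {category}.
    Write a supportive response that addresses this risk signal.

    Post: {post}
AI-3:
  description: post + IPTS category + supportive-response characteristics
  prompt: |
    You are replying in an online peer-support community. The post below has
    been categorized under the Interpersonal Theory of Suicide as: {category}.
    Write a supportive response that is (1) semantically similar and
    linguistically accommodating to the post, (2) diverse, (3) empathetic,
    and (4) promoting hopefulness.

    Post: {post}
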