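states:
- name: Begin
  emitting: false
  class: null
- name: M.begin
  emitting: true
  class: M
- name: M.interior
  emitting: true
  class: M
- name: M.end
  emitting: true
  class: M
- name: H.begin
  emitting: true
  class: H
- name: H.interior
  emitting: true
  class: H
- name: H.end
  emitting: true
  class: H
- name: E.begin
  emitting: true
  class: E
- name: E.interior
  emitting: true
  class: E
- name: E.end
  emitting: true
  class: E
- name: C
  emitting: true
  class: C
- name: End
  emitting: false
  class: null
begin: Begin
end: End
edges:
- - Begin
  - M.begin
- - Begin
  - H.begin
- - Begin
  - E.begin
- - Begin
  - C
- - M.begin
  - M.interior
- - M.interior
  - M.interior
- - M.interior
  - M.end
- - M.end
  - H.begin
- - M.end
  - E.begin
- - M.end
  - C
- - M.end
  - End
- - H.begin
  - H.interior
- - H.interior
  - H.interior
- - H.interior
  - H.end
- - H.end
  - M.begin
- - H.end
  - E.begin
- - H.end
  - C
- - H.end
  - End
- - E.begin
  - E.interior
- - E.interior
  - E.interior
- - E.interior
  - E.end
- - E.end
  - M.begin
- - E.end
  - H.begin
- - E.end
  - C
- - E.end
  - End
- - C
  - M.begin
- - C
  - H.begin
- - C
  - E.begin
- - C
  - C
- - C
  - End
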